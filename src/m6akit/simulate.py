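"""Synthetic data with planted ground truth for every pipeline stage.

Counts are negative-binomial (gamma-Poisson) with log-normal gene baseline
means and uniform[0.5, 2] library-size factors, so normalization is always
exercised. Methylation state propagates down the hierarchy by a first-order
Markov rule on the immediate parent: a child gene is methylated with
probability ``p_inherit`` when the parent is methylated and ``p_denovo``
otherwise. One global seed spawns an independent RNG stream per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import CountMatrix, HierarchyTree, SampleSheet
from .kinetics import DecayCurve

ORIGIN_ROOT = "root_set"
ORIGIN_INHERITED = "inherited"
ORIGIN_DENOVO = "de_novo"
ORIGIN_ABSENT = "absent"


@dataclass
class SimulationParams:
    """Knobs for the landscape simulator; bounds validated on construction."""

    n_genes: int
    tree: HierarchyTree
    frac_methylated_root: float = 0.3
    p_inherit: float = 0.8
    p_denovo: float = 0.1
    enrichment_lfc: float = 2.0
    dispersion: float = 0.1
    mean_depth: float = 50.0
    n_reps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if not self.tree.nodes:
            raise ParameterError("tree must be non-empty")
        for name in ("frac_methylated_root", "p_inherit", "p_denovo"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.enrichment_lfc <= 0:
            raise ParameterError("enrichment_lfc must be positive")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be positive")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")


@dataclass
class LandscapeTruth:
    """Planted (gene, population) methylation states and origins.

    ``methylated`` and ``true_lfc`` are gene x population DataFrames;
    ``origin`` holds root_set/inherited/de_novo/absent labels. The realized
    size factors and baseline means are kept for oracle checks.
    """

    methylated: pd.DataFrame
    origin: pd.DataFrame
    true_lfc: pd.DataFrame
    size_factors: pd.Series = field(default=None)
    baseline_means: pd.Series = field(default=None)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson NB sample with variance mu + alpha*mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def _topological_order(tree: HierarchyTree) -> list[str]:
    order = [tree.root]
    frontier = [tree.root]
    while frontier:
        nxt: list[str] = []
        for node in frontier:
            for child in tree.children(node):
                order.append(child)
                nxt.append(child)
        frontier = nxt
    return order


def simulate_landscape_counts(params: SimulationParams
                              ) -> tuple[CountMatrix, SampleSheet, LandscapeTruth]:
    """Paired IP/INPUT NB counts for every tree population, plus truth.

    INPUT counts ~ NB(mu_g * s_j, alpha); IP counts multiply the mean by
    2^true_lfc for methylated genes.
    """
    tree = params.tree
    pops = _topological_order(tree)
    genes = [f"G{i + 1:05d}" for i in range(params.n_genes)]

    ss = np.random.SeedSequence(params.seed)
    rng_state, rng_mean, rng_size, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # methylation states down the tree (first-order Markov on the parent)
    meth = pd.DataFrame(False, index=genes, columns=pops)
    origin = pd.DataFrame(ORIGIN_ABSENT, index=genes, columns=pops)
    meth[tree.root] = rng_state.random(params.n_genes) < params.frac_methylated_root
    origin.loc[meth[tree.root], tree.root] = ORIGIN_ROOT
    for pop in pops[1:]:
        parent = tree.parent[pop]
        u = rng_state.random(params.n_genes)
        parent_meth = meth[parent].to_numpy()
        is_meth = np.where(parent_meth, u < params.p_inherit, u < params.p_denovo)
        meth[pop] = is_meth
        origin.loc[is_meth & parent_meth, pop] = ORIGIN_INHERITED
        origin.loc[is_meth & ~parent_meth, pop] = ORIGIN_DENOVO
    true_lfc = meth.astype(float) * params.enrichment_lfc

    # expression baselines: log-normal with sdlog 1, median = mean_depth
    mu = rng_mean.lognormal(mean=np.log(params.mean_depth), sigma=1.0,
                            size=params.n_genes)

    sample_rows = []
    sample_ids: list[str] = []
    for pop in pops:
        for assay in ("IP", "INPUT"):
            for rep in range(1, params.n_reps + 1):
                sid = f"{pop}_{assay}_rep{rep}"
                sample_ids.append(sid)
                sample_rows.append({"sample_id": sid, "population": pop,
                                    "assay": assay, "condition": "WT",
                                    "replicate": rep})
    s = rng_size.uniform(0.5, 2.0, size=len(sample_ids))

    counts = np.empty((params.n_genes, len(sample_ids)), dtype=np.int64)
    for j, row in enumerate(sample_rows):
        base = mu * s[j]
        if row["assay"] == "IP":
            base = base * np.exp2(true_lfc[row["population"]].to_numpy())
        counts[:, j] = _nb_draw(rng_counts, base, params.dispersion)

    cm = CountMatrix(genes, sample_ids, counts)
    sheet = SampleSheet(pd.DataFrame(sample_rows))
    truth = LandscapeTruth(meth, origin, true_lfc,
                           size_factors=pd.Series(s, index=sample_ids),
                           baseline_means=pd.Series(mu, index=genes))
    return cm, sheet, truth


def simulate_de_counts(n_genes: int, n_reps: int, frac_de: float, lfc_de: float,
                       dispersion: float, mean_depth: float, seed: int
                       ) -> tuple[CountMatrix, SampleSheet, pd.Series]:
    """WT/KO NB counts with a planted DE subset (random, sign-balanced).

    Returns truth flags per gene: +1 (up in KO), -1 (down in KO), 0 (null).
    """
    if not (0.0 <= frac_de <= 1.0):
        raise ParameterError("frac_de must lie in [0, 1]")
    if lfc_de < 0:
        raise ParameterError("lfc_de must be >= 0")
    if dispersion < 0:
        raise ParameterError("dispersion must be >= 0")
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    if n_reps < 1 or n_genes < 1:
        raise ParameterError("n_genes and n_reps must be >= 1")

    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    ss = np.random.SeedSequence(seed)
    rng_truth, rng_mean, rng_size, rng_counts = (
        np.random.default_rng(x) for x in ss.spawn(4)
    )
    is_de = rng_truth.random(n_genes) < frac_de
    sign = np.where(rng_truth.random(n_genes) < 0.5, 1.0, -1.0)
    flags = pd.Series(np.where(is_de, sign, 0.0).astype(int), index=genes,
                      name="de_direction")

    mu = rng_mean.lognormal(mean=np.log(mean_depth), sigma=1.0, size=n_genes)
    shift = np.exp2(flags.to_numpy() * lfc_de)

    sample_rows = []
    sample_ids = []
    for cond in ("WT", "KO"):
        for rep in range(1, n_reps + 1):
            sid = f"{cond}_rep{rep}"
            sample_ids.append(sid)
            sample_rows.append({"sample_id": sid, "population": "SSC",
                                "assay": "INPUT", "condition": cond,
                                "replicate": rep})
    s = rng_size.uniform(0.5, 2.0, size=len(sample_ids))
    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    for j, row in enumerate(sample_rows):
        base = mu * s[j]
        if row["condition"] == "KO":
            base = base * shift
        counts[:, j] = _nb_draw(rng_counts, base, dispersion)

    return (CountMatrix(genes, sample_ids, counts),
            SampleSheet(pd.DataFrame(sample_rows)), flags)


def simulate_decay(true_half_life_h: float, times_h, noise_sd: float,
                   n_curves: int, seed: int) -> tuple[list[DecayCurve], float]:
    """Exponential decay curves with multiplicative log-normal noise.

    C/C0(t) = 2^(-t/t_half) * exp(eps), eps ~ N(0, noise_sd); the t = 0
    point is fixed at exactly 1. Returns the curves and the true half-life.
    """
    if true_half_life_h <= 0:
        raise ParameterError("true half-life must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if n_curves < 1:
        raise ParameterError("n_curves must be >= 1")
    times = np.asarray(times_h, dtype=float)
    if 0.0 not in times:
        raise ParameterError("times must include 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ideal = np.exp2(-times / true_half_life_h)
    curves = []
    for _ in range(n_curves):
        eps = rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else 0.0
        rel = ideal * np.exp(eps)
        rel = np.where(times == 0.0, 1.0, rel)
        curves.append(DecayCurve(times, rel))
    return curves, float(true_half_life_h)


def default_tree() -> HierarchyTree:
    """The documented default skeletal hierarchy fixture: a stem/progenitor
    chain with five downstream populations under the third stage."""
    edges = [("SSC", "pBCSP"), ("pBCSP", "BCSP"),
             ("BCSP", "PCP"), ("BCSP", "Thy"), ("BCSP", "BLSP"),
             ("BCSP", "6C3"), ("BCSP", "HEC")]
    nodes = ["SSC", "pBCSP", "BCSP", "PCP", "Thy", "BLSP", "6C3", "HEC"]
    return HierarchyTree(nodes, edges)
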