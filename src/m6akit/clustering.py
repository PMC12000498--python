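"""m6A / expression integration: feature building, K-means, correlation
signs and hypergeometric gene-set enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import ParameterError
from .io import GeneSetCollection
from .landscape import M6ALandscape
from .nbtest import benjamini_hochberg


@dataclass
class ClusterAssignment:
    """Gene -> cluster label (1..K), renumbered by descending cluster size."""

    labels: pd.Series  # index gene_id, values 1..K
    k: int
    seed: int
    n_init: int
    inertia: float


def build_feature_matrix(landscape: M6ALandscape, expression: pd.DataFrame,
                         genes: list[str] | None = None) -> pd.DataFrame:
    """Concatenate mean-centered m6A and expression profiles per gene.

    ``expression`` is a gene x population table of normalized mean counts;
    the expression channel is log2(x + 1). Both channels are row-centered
    and then scaled so each channel's pooled variance is 1. Only genes with
    complete rows in both channels (intersected with ``genes`` if given)
    are kept.
    """
    pops = landscape.populations
    missing = [p for p in pops if p not in expression.columns]
    if missing:
        raise ParameterError(f"expression table lacks population(s) {missing}")
    expr = expression[pops]

    z_complete = landscape.z.dropna()
    keep = z_complete.index.intersection(expr.dropna().index)
    if genes is not None:
        keep = keep.intersection(pd.Index(genes))
    if len(keep) == 0:
        raise ParameterError("no gene has complete m6A and expression profiles")
    keep = [g for g in landscape.gene_ids if g in set(keep)]  # stable order

    m6a = landscape.z.loc[keep, pops]
    logexpr = np.log2(expr.loc[keep, pops] + 1.0)

    def center_and_scale(block: pd.DataFrame) -> pd.DataFrame:
        centered = block.sub(block.mean(axis=1), axis=0)
        pooled_sd = float(np.sqrt((centered.to_numpy() ** 2).mean()))
        return centered / pooled_sd if pooled_sd > 0 else centered

    m6a_c = center_and_scale(m6a)
    expr_c = center_and_scale(logexpr)
    m6a_c.columns = [f"m6a:{p}" for p in pops]
    expr_c.columns = [f"expr:{p}" for p in pops]
    return pd.concat([m6a_c, expr_c], axis=1)


def kmeans_cluster(matrix: pd.DataFrame, k: int, seed: int,
                   n_init: int = 10) -> ClusterAssignment:
    """Lloyd's K-means with k-means++ init and n_init restarts.

    Labels are renumbered 1..K by descending cluster size (ties broken by
    the smallest member gene id) so output is stable across runs.
    """
    if k < 1:
        raise ParameterError("K must be >= 1")
    if k > matrix.shape[0]:
        raise ParameterError(f"K={k} exceeds number of rows {matrix.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(matrix.to_numpy())

    order = sorted(
        range(k),
        key=lambda lab: (-(raw == lab).sum(),
                         min((g for g, l in zip(matrix.index, raw) if l == lab),
                             default="")),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[l] for l in raw], index=matrix.index, name="cluster")
    return ClusterAssignment(labels, k, seed, n_init, float(km.inertia_))


def cluster_correlation_sign(assignment: ClusterAssignment,
                             landscape: M6ALandscape,
                             expression: pd.DataFrame,
                             method: str = "pearson") -> pd.DataFrame:
    """Per cluster: correlation across populations between the cluster-mean
    m6A profile and the cluster-mean log expression profile."""
    pops = landscape.populations
    if len(pops) < 3:
        raise ParameterError("correlation needs >=3 populations")
    logexpr = np.log2(expression[pops] + 1.0)
    rows = []
    for cluster in sorted(assignment.labels.unique()):
        genes = assignment.labels.index[assignment.labels == cluster]
        m6a_profile = landscape.z.loc[genes, pops].mean(axis=0).to_numpy()
        expr_profile = logexpr.loc[genes].mean(axis=0).to_numpy()
        if np.std(m6a_profile) == 0 or np.std(expr_profile) == 0:
            rows.append({"cluster": cluster, "n_genes": len(genes), "r": np.nan,
                         "p_value": np.nan, "sign": "undefined"})
            continue
        if method == "pearson":
            r, p = stats.pearsonr(m6a_profile, expr_profile)
        elif method == "spearman":
            r, p = stats.spearmanr(m6a_profile, expr_profile)
        else:
            raise ParameterError(f"unknown correlation method {method!r}")
        rows.append({"cluster": cluster, "n_genes": len(genes), "r": float(r),
                     "p_value": float(p),
                     "sign": "positive" if r > 0 else ("negative" if r < 0 else "zero")})
    return pd.DataFrame(rows, columns=["cluster", "n_genes", "r", "p_value", "sign"])


def hypergeometric_enrichment(selected: set[str], collection: GeneSetCollection,
                              universe: set[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selected`` in each set.

    p = P(X >= k) with N = |universe|, K = |set ∩ universe|,
    n = |selected|, k = |selected ∩ set|. BH adjustment across sets.
    """
    if not universe:
        raise ParameterError("universe must be non-empty")
    if not set(selected) <= set(universe):
        raise ParameterError("selected genes must be a subset of the universe")
    n_universe = len(universe)
    n_selected = len(selected)
    rows = []
    for name, members in collection.sets.items():
        annotated = members & universe
        overlap = selected & annotated
        k = len(overlap)
        big_k = len(annotated)
        # P(X >= k); sf(k-1) is exact for the discrete upper tail
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_selected)) if k > 0 else 1.0
        rows.append({"set_name": name, "universe_size": n_universe,
                     "annotated": big_k, "selected": n_selected,
                     "overlap": k, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set_name", "universe_size", "annotated",
                                     "selected", "overlap", "p_value"])
    if len(df):
        df["padj"] = benjamini_hochberg(df["p_value"].to_numpy())
    else:
        df["padj"] = []
    return df
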