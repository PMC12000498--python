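"""Meta-epitranscriptomic map assembly.

Per population, the relative m6A level of a gene is the Z-score of its
IP-vs-input Wald statistic across all scored genes in that population
(population-SD, divisor n). High-confidence targets are genes passing
strict log2 fold-change and p-value cutoffs. Genes filtered out of a
population's test are *missing* there (NaN), not non-targets, and do not
enter that population's Z normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .nbtest import EnrichmentResult

DEFAULT_LFC_THRESH = 1.0
DEFAULT_P_THRESH = 0.05


@dataclass
class M6ALandscape:
    """Gene x population relative m6A Z-scores plus target mask.

    ``z`` and ``is_target`` are DataFrames indexed by gene id with one
    column per population; cells where a gene was not scored are NaN in
    both (``is_target`` uses a nullable boolean dtype).
    """

    z: pd.DataFrame
    is_target: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return list(self.z.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    def targets_in(self, population: str) -> set[str]:
        col = self.is_target[population]
        return set(col.index[col.fillna(False).astype(bool)])

    def to_long(self) -> pd.DataFrame:
        """Tidy (gene, population, z, is_target) rows for scored cells."""
        records = []
        for pop in self.populations:
            scored = self.z[pop].notna()
            for gene in self.z.index[scored]:
                records.append({
                    "gene_id": gene, "population": pop,
                    "z": self.z.at[gene, pop],
                    "is_target": bool(self.is_target.at[gene, pop]),
                })
        return pd.DataFrame(records, columns=["gene_id", "population", "z", "is_target"])


def relative_m6a_zscore(wald_stats: Sequence[float]) -> np.ndarray:
    """Z-score of the Wald statistic over all scored genes of one population.

    Uses the population SD (divisor n), so a symmetric pair maps to -1/+1
    and mean(z) = 0, sd(z) = 1 exactly.
    """
    w = np.asarray(wald_stats, dtype=float)
    if w.size < 2:
        raise ParameterError("Z-score needs >=2 scored genes")
    sd = w.std(ddof=0)
    if sd == 0:
        raise DegenerateInputError("Wald statistics are constant; Z-score undefined")
    return (w - w.mean()) / sd


def call_targets(result: EnrichmentResult,
                 lfc_thresh: float = DEFAULT_LFC_THRESH,
                 p_thresh: float = DEFAULT_P_THRESH,
                 use_adjusted: bool = False) -> pd.Series:
    """High-confidence target mask: log2fc > lfc_thresh AND p < p_thresh.

    Both inequalities are strict. ``use_adjusted`` switches the p column to
    the BH-adjusted values.
    """
    if lfc_thresh <= 0:
        raise ParameterError("lfc_thresh must be positive")
    if not (0 < p_thresh <= 1):
        raise ParameterError("p_thresh must lie in (0, 1]")
    t = result.table
    p = t["padj"] if use_adjusted else t["p_value"]
    mask = (t["log2fc"] > lfc_thresh) & (p < p_thresh)
    return pd.Series(mask.to_numpy(), index=t["gene_id"].to_numpy(), name="is_target")


def assemble_landscape(results: Mapping[str, EnrichmentResult],
                       lfc_thresh: float = DEFAULT_LFC_THRESH,
                       p_thresh: float = DEFAULT_P_THRESH,
                       use_adjusted: bool = False) -> M6ALandscape:
    """Combine per-population enrichment results into one landscape.

    The gene universe is the union over populations; a gene unscored in a
    population is NaN in both channels there.
    """
    populations = list(results)
    if len(populations) == 0:
        raise ParameterError("need >=1 population")
    if len(set(populations)) != len(populations):
        raise ParameterError("duplicated population in results")

    all_genes: list[str] = []
    seen: set[str] = set()
    for pop in populations:
        for g in results[pop].table["gene_id"]:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)

    z = pd.DataFrame(np.nan, index=pd.Index(all_genes, name="gene_id"),
                     columns=populations)
    is_target = pd.DataFrame(pd.NA, index=z.index, columns=populations,
                             dtype="boolean")
    for pop in populations:
        t = results[pop].table
        zvals = relative_m6a_zscore(t["wald_stat"].to_numpy())
        z.loc[t["gene_id"].to_numpy(), pop] = zvals
        mask = call_targets(results[pop], lfc_thresh, p_thresh, use_adjusted)
        is_target.loc[mask.index, pop] = mask.to_numpy()

    return M6ALandscape(z, is_target, provenance={
        "lfc_thresh": lfc_thresh, "p_thresh": p_thresh,
        "use_adjusted": use_adjusted, "populations": populations,
    })


def union_target_count(landscape: M6ALandscape) -> int:
    """Genes that are a target in at least one population."""
    return int(landscape.is_target.fillna(False).astype(bool).any(axis=1).sum())


def mean_center_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene row's cross-population mean (idempotent)."""
    return profiles.sub(profiles.mean(axis=1), axis=0)
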