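"""Origin of m6A targets along the developmental hierarchy.

A target in the root population is ``root_set``. A target in a non-root
population is ``inherited`` when the same gene is a target in the immediate
parent (mode ``parent``) or in any population on the path to the root (mode
``any_ancestor``, the default); otherwise it is ``de_novo``. Cells missing
from an ancestor's landscape count as absent: inheritance requires positive
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, StructureError
from .io import HierarchyTree
from .landscape import M6ALandscape

ORIGIN_ROOT = "root_set"
ORIGIN_INHERITED = "inherited"
ORIGIN_DENOVO = "de_novo"

MODES = ("parent", "any_ancestor")


@dataclass
class InheritanceTable:
    """Per-(population, gene) origin labels for called targets."""

    table: pd.DataFrame  # population, gene_id, origin, evidence
    mode: str

    def __len__(self) -> int:
        return len(self.table)


def classify_inheritance(landscape: M6ALandscape, tree: HierarchyTree,
                         mode: str = "any_ancestor") -> InheritanceTable:
    """Label every called target root_set / inherited / de_novo.

    ``evidence`` carries the nearest upstream population in which the gene
    is also a target (empty for root_set and de_novo).
    """
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    node_set = set(tree.nodes)
    for pop in landscape.populations:
        if pop not in node_set:
            raise StructureError(f"population {pop!r} is not a node of the hierarchy")

    target_sets = {pop: landscape.targets_in(pop) for pop in landscape.populations}
    rows = []
    for pop in landscape.populations:
        if pop == tree.root:
            for gene in sorted(target_sets[pop]):
                rows.append((pop, gene, ORIGIN_ROOT, ""))
            continue
        upstream = tree.ancestors(pop)  # parent first, root last
        if mode == "parent":
            upstream = upstream[:1]
        upstream = [a for a in upstream if a in target_sets]
        for gene in sorted(target_sets[pop]):
            evidence = next((a for a in upstream if gene in target_sets[a]), None)
            if evidence is None:
                rows.append((pop, gene, ORIGIN_DENOVO, ""))
            else:
                rows.append((pop, gene, ORIGIN_INHERITED, evidence))
    table = pd.DataFrame(rows, columns=["population", "gene_id", "origin", "evidence"])
    return InheritanceTable(table, mode)


def stage_fractions(table: InheritanceTable) -> pd.DataFrame:
    """Per population: target count and origin fractions.

    Populations with zero targets report NaN fractions rather than 0.
    """
    rows = []
    for pop, grp in table.table.groupby("population", sort=False):
        n = len(grp)
        counts = grp["origin"].value_counts()
        rows.append({
            "population": pop,
            "n_targets": n,
            "frac_root_set": counts.get(ORIGIN_ROOT, 0) / n if n else np.nan,
            "frac_inherited": counts.get(ORIGIN_INHERITED, 0) / n if n else np.nan,
            "frac_de_novo": counts.get(ORIGIN_DENOVO, 0) / n if n else np.nan,
        })
    return pd.DataFrame(rows, columns=["population", "n_targets", "frac_root_set",
                                       "frac_inherited", "frac_de_novo"])


def aggregate_group_fraction(table: InheritanceTable, populations: list[str],
                             origin: str) -> dict:
    """Pooled fraction of an origin label over a subset of populations.

    Returns the pooled fraction, the per-population maximum, and the pooled
    target count.
    """
    if not populations:
        raise ParameterError("population subset must be non-empty")
    sub = table.table[table.table["population"].isin(populations)]
    n = len(sub)
    if n == 0:
        return {"fraction": np.nan, "max_population_fraction": np.nan, "n_targets": 0}
    pooled = float((sub["origin"] == origin).sum() / n)
    per_pop = sub.groupby("population")["origin"].apply(
        lambda s: (s == origin).mean()
    )
    return {"fraction": pooled,
            "max_population_fraction": float(per_pop.max()),
            "n_targets": n}
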