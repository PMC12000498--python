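"""KO-vs-WT differential expression overlaid with m6A target status."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError
from .landscape import M6ALandscape
from .nbtest import EnrichmentResult

DEFAULT_DEG_LFC_THRESH = 0.5
DEFAULT_DEG_P_THRESH = 0.05

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NS = "ns"


@dataclass
class DEGTable:
    """Per-gene DE call (direction up/down/ns) with optional m6A tagging."""

    table: pd.DataFrame  # gene_id, log2fc, p_value, direction[, m6a_tagged]
    lfc_thresh: float
    p_thresh: float

    def __len__(self) -> int:
        return len(self.table)


def call_degs(result: EnrichmentResult,
              lfc_thresh: float = DEFAULT_DEG_LFC_THRESH,
              p_thresh: float = DEFAULT_DEG_P_THRESH,
              use_adjusted: bool = False) -> DEGTable:
    """Direction calls with strict cutoffs: up iff log2fc > lfc_thresh and
    p < p_thresh; down symmetric; otherwise ns."""
    if lfc_thresh <= 0:
        raise ParameterError("lfc_thresh must be positive")
    if not (0 < p_thresh <= 1):
        raise ParameterError("p_thresh must lie in (0, 1]")
    t = result.table
    p = t["padj"] if use_adjusted else t["p_value"]
    direction = pd.Series(DIRECTION_NS, index=t.index, dtype=object)
    direction[(t["log2fc"] > lfc_thresh) & (p < p_thresh)] = DIRECTION_UP
    direction[(t["log2fc"] < -lfc_thresh) & (p < p_thresh)] = DIRECTION_DOWN
    out = pd.DataFrame({
        "gene_id": t["gene_id"].to_numpy(),
        "log2fc": t["log2fc"].to_numpy(),
        "p_value": t["p_value"].to_numpy(),
        "padj": t["padj"].to_numpy(),
        "direction": direction.to_numpy(),
    })
    return DEGTable(out, lfc_thresh, p_thresh)


def overlay_m6a(degs: DEGTable, landscape: M6ALandscape, population: str) -> dict:
    """Tag DEGs with m6A target status in the given population.

    Returns counts and gene lists for the up&tagged / down&tagged sets and
    the tagged DEG table (a new DEGTable with an ``m6a_tagged`` column).
    """
    if population not in landscape.populations:
        raise ParameterError(f"population {population!r} not in landscape")
    targets = landscape.targets_in(population)
    t = degs.table.copy()
    t["m6a_tagged"] = t["gene_id"].isin(targets)
    up = t[(t["direction"] == DIRECTION_UP) & t["m6a_tagged"]]["gene_id"].tolist()
    down = t[(t["direction"] == DIRECTION_DOWN) & t["m6a_tagged"]]["gene_id"].tolist()
    return {
        "table": DEGTable(t, degs.lfc_thresh, degs.p_thresh),
        "population": population,
        "n_up_tagged": len(up),
        "n_down_tagged": len(down),
        "n_tagged_degs": len(up) + len(down),
        "up_tagged_genes": sorted(up),
        "down_tagged_genes": sorted(down),
    }
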