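"""mRNA decay kinetics and delta-delta-Ct quantification.

First-order decay dC/dt = -k*C gives ln(C/C0) = -k*t; the decay constant is
the least-squares slope of log relative abundance on time (through the
origin by default, since C0 normalizes the t=0 point to 1) and the
half-life is ln2/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError

LN2 = math.log(2.0)


@dataclass
class DecayCurve:
    """Relative abundance C/C0 over time; times include 0 where C/C0 = 1."""

    times: np.ndarray
    rel_abundance: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if self.times.shape != self.rel_abundance.shape:
            raise ParameterError("times and abundances must have equal length")
        if (np.diff(self.times) <= 0).any():
            raise ParameterError("times must be strictly increasing")
        if (self.rel_abundance <= 0).any():
            raise ParameterError("relative abundance must be positive")


@dataclass
class DecayFit:
    k_decay: float          # per hour, >= 0 (negative slopes clamped)
    t_half: float           # hours; inf when k_decay == 0
    r_squared: float
    n_points: int
    flag: str = ""          # "stable" when clamped / zero decay


@dataclass
class DdCtResult:
    delta_delta_ct: float
    fold: float
    normalizer: str


def decay_fit(curve: DecayCurve, intercept: str = "fixed_zero") -> DecayFit:
    """Fit ln(C/C0) = -k*t by least squares.

    ``intercept='fixed_zero'`` regresses through the origin (needs >=2
    points with t > 0 after replicate averaging); ``'free'`` fits an
    intercept too (needs >=3 points). Replicate observations at the same
    time are averaged on the log scale first. A negative decay estimate
    (apparent growth) is clamped to k = 0 and flagged ``stable``.
    """
    if intercept not in ("fixed_zero", "free"):
        raise ParameterError(f"unknown intercept mode {intercept!r}")
    t_all = curve.times
    logy_all = np.log(curve.rel_abundance)
    # average replicates sharing a time point on the log scale
    uniq = np.unique(t_all)
    t = uniq
    logy = np.array([logy_all[t_all == u].mean() for u in uniq])

    n_pos = int((t > 0).sum())
    if intercept == "fixed_zero":
        if n_pos < 2:
            raise ParameterError("fixed-zero fit needs >=2 time points with t > 0")
        denom = float((t**2).sum())
        if denom == 0:
            raise ParameterError("all time points are zero")
        slope = float((t * logy).sum() / denom)
        fitted = slope * t
    else:
        if len(t) < 3:
            raise ParameterError("free-intercept fit needs >=3 time points")
        slope, icept = np.polyfit(t, logy, 1)
        slope = float(slope)
        fitted = slope * t + icept

    ss_res = float(((logy - fitted) ** 2).sum())
    ss_tot = float(((logy - logy.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else (1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)

    k = -slope
    flag = ""
    if k < 0:
        k, flag = 0.0, "stable"
    elif k == 0:
        flag = "stable"
    return DecayFit(k_decay=k, t_half=half_life(k), r_squared=r2,
                    n_points=len(t), flag=flag)


def half_life(k_decay: float) -> float:
    """t1/2 = ln2 / k; infinite at k = 0."""
    if k_decay < 0:
        raise ParameterError("decay constant must be >= 0")
    if k_decay == 0:
        return math.inf
    return LN2 / k_decay


def ddct_quantify(ct_target_ip: float, ct_target_input: float,
                  ct_ref_ip: float, ct_ref_input: float,
                  normalizer: str = "input") -> DdCtResult:
    """2^(-ddCt) relative quantification against the input fraction.

    ddCt = (Ct_target_IP - Ct_ref_IP) - (Ct_target_input - Ct_ref_input).
    """
    for name, v in (("ct_target_ip", ct_target_ip), ("ct_target_input", ct_target_input),
                    ("ct_ref_ip", ct_ref_ip), ("ct_ref_input", ct_ref_input)):
        if not math.isfinite(v):
            raise ParameterError(f"{name} must be finite")
    ddct = (ct_target_ip - ct_ref_ip) - (ct_target_input - ct_ref_input)
    return DdCtResult(delta_delta_ct=ddct, fold=2.0 ** (-ddct), normalizer=normalizer)


def fit_decay_table(rows: Sequence[tuple[str, float, float]],
                    intercept: str = "fixed_zero") -> dict[str, DecayFit]:
    """Fit one curve per gene from (gene, time_h, rel_abundance) rows."""
    by_gene: dict[str, list[tuple[float, float]]] = {}
    for gene, time_h, rel in rows:
        by_gene.setdefault(str(gene), []).append((float(time_h), float(rel)))
    out: dict[str, DecayFit] = {}
    for gene, pts in by_gene.items():
        pts.sort()
        times = np.array([p[0] for p in pts])
        rels = np.array([p[1] for p in pts])
        # DecayCurve wants strictly increasing times; replicates are kept by
        # passing them through the averaging in decay_fit via tiny grouping
        order = np.argsort(times, kind="stable")
        times, rels = times[order], rels[order]
        # collapse exact duplicates is done inside decay_fit; DecayCurve
        # validation requires strict increase, so pre-average here instead
        uniq = np.unique(times)
        logmean = np.array([np.log(rels[times == u]).mean() for u in uniq])
        curve = DecayCurve(uniq, np.exp(logmean))
        out[gene] = decay_fit(curve, intercept=intercept)
    return out
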