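"""Stress-regulation calls: TPTM normalization and the Audic-Claverie test.

For tag counts x (control, depth N1) and y (stress, depth N2) the
Audic-Claverie posterior mass is

    p(y | x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

algebraically the negative-binomial pmf NB(r = x+1, p = N1/(N1+N2)) in y.
Tails are accumulated by direct log-space summation of this mass function
(stable for arbitrarily deep tails, where generic cdf/sf routines
underflow) and the smaller tail is doubled, capped at 1, for a two-sided
p-value. A miRNA is called stress-regulated
only when all three conditions hold: at least 100 TPTM in either library,
|log2 ratio| of normalized expression above 1, and p <= 0.01. No
multiple-testing correction is applied by default (a Benjamini-Hochberg
flag is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .biogenesis import tptm
from .config import PipelineConfig

STRESSES = ("drought", "cold", "salt")


@dataclass
class DifferentialCall:
    mirna: str
    stress: str
    x: int
    y: int
    n1: int
    n2: int
    tptm_ctrl: float
    tptm_stress: float
    log2_ratio: float
    p: float
    verdict: str  # up | down | unchanged


def _ac_logpmf(k: np.ndarray, x: int, log_ratio: float,
               log1p_ratio: float) -> np.ndarray:
    return (k * log_ratio + gammaln(x + k + 1) - gammaln(x + 1)
            - gammaln(k + 1) - (x + k + 1) * log1p_ratio)


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts x@N1 vs y@N2.

    p = min(1, 2 * min(P(Y <= y | x), P(Y >= y | x))), both inclusive tails
    summed in log space directly from the mass function.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library depths must be positive")
    lr = math.log(n2 / n1)
    ls = math.log1p(n2 / n1)
    lower = logsumexp(_ac_logpmf(np.arange(0, y + 1), x, lr, ls))
    mean = (x + 1) * n2 / n1
    kmax = int(max(y, mean) + 12 * math.sqrt(mean + 10) + 100)
    while True:
        terms = _ac_logpmf(np.arange(y, kmax + 1), x, lr, ls)
        upper = logsumexp(terms)
        if terms[-1] < upper - 46:  # remainder below ~1e-20 of the tail
            break
        kmax *= 2
    # tails far below float resolution clamp to the smallest positive value
    return float(min(1.0, max(2.0 * math.exp(min(lower, upper)), 5e-324)))


def log2_ratio(tptm_stress: float, tptm_ctrl: float,
               depth_stress: int, depth_ctrl: int, scale: float = 1e7) -> float:
    """log2 of the normalized-expression ratio with a one-read pseudocount.

    A zero TPTM on either side is replaced by the TPTM of a single read in
    that library; both-zero input is undefined (NaN) and excluded from
    calling.
    """
    if tptm_stress < 0 or tptm_ctrl < 0:
        raise ValueError("TPTM values must be non-negative")
    if tptm_stress == 0 and tptm_ctrl == 0:
        return math.nan
    if tptm_stress == 0:
        tptm_stress = tptm(1, depth_stress, scale)
    if tptm_ctrl == 0:
        tptm_ctrl = tptm(1, depth_ctrl, scale)
    return math.log2(tptm_stress / tptm_ctrl)


def _bh_adjust(pvals: list[float]) -> list[float]:
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, pvals[i] * n / (rank + 1))
        adj[i] = running
    return adj.tolist()


def call_stress_regulated(counts: pd.DataFrame, depths: dict[str, int],
                          config: PipelineConfig | None = None,
                          ) -> list[DifferentialCall]:
    """Three-criterion stress-regulation calls for each miRNA and stress.

    ``counts`` has miRNA identifiers as index and raw counts in columns
    named control/drought/cold/salt; ``depths`` are the libraries' clean
    read totals.
    """
    cfg = config or PipelineConfig()
    calls: list[DifferentialCall] = []
    for stress in STRESSES:
        if stress not in counts.columns:
            continue
        per_stress: list[DifferentialCall] = []
        for mirna, row in counts.iterrows():
            x = int(row["control"])
            y = int(row[stress])
            n1, n2 = depths["control"], depths[stress]
            t_ctrl = tptm(x, n1, cfg.tptm_scale)
            t_str = tptm(y, n2, cfg.tptm_scale)
            lr = log2_ratio(t_str, t_ctrl, n2, n1, cfg.tptm_scale)
            p = ac_pvalue(x, y, n1, n2)
            verdict = "unchanged"
            if (max(t_ctrl, t_str) >= cfg.de_tptm_min
                    and not math.isnan(lr) and abs(lr) > cfg.de_log2_min
                    and p <= cfg.de_p_max):
                verdict = "up" if lr > 0 else "down"
            per_stress.append(DifferentialCall(
                mirna=str(mirna), stress=stress, x=x, y=y, n1=n1, n2=n2,
                tptm_ctrl=t_ctrl, tptm_stress=t_str, log2_ratio=lr, p=p,
                verdict=verdict))
        if cfg.de_fdr and per_stress:
            adj = _bh_adjust([c.p for c in per_stress])
            for c, q in zip(per_stress, adj):
                if c.verdict != "unchanged" and q > cfg.de_p_max:
                    c.verdict = "unchanged"
        calls.extend(per_stress)
    return calls


def calls_to_frame(calls: list[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
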