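"""Independent brute-force reference implementations used as test oracles.

Deliberately naive (full scans, direct summation) and kept free of any
code from the package's optimized paths.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_map(genome: dict[str, str], read: str) -> list[tuple[str, int, str]]:
    """Every exact occurrence on both strands by scanning every position."""
    out = []
    for chrom, g in genome.items():
        L = len(read)
        for i in range(len(g) - L + 1):
            if g[i:i + L] == read:
                out.append((chrom, i, "+"))
            if g[i:i + L] == rc(read):
                out.append((chrom, i, "-"))
    return out


def naive_copy_number(genome: dict[str, str], read: str,
                      max_mismatch: int = 2) -> int:
    n = 0
    for g in genome.values():
        L = len(read)
        for i in range(len(g) - L + 1):
            w = g[i:i + L]
            if sum(a != b for a, b in zip(w, read)) <= max_mismatch:
                n += 1
            if sum(a != b for a, b in zip(w, rc(read))) <= max_mismatch:
                n += 1
    return n


def naive_distance(a: str, b: str) -> int:
    """Mismatches of the best ungapped overlap alignment, enumerating every
    offset with overlap >= min(len) - 2; unaligned shorter-sequence
    positions count as mismatches."""
    la, lb = len(a), len(b)
    short = min(la, lb)
    best = short
    for off in range(-la, lb + 1):
        lo, hi = max(0, -off), min(la, lb - off)
        if hi - lo < short - 2:
            continue
        subs = sum(a[i] != b[i + off] for i in range(lo, hi))
        best = min(best, subs + short - (hi - lo))
    return best


def naive_clusters(seqs: list[str], max_mismatch: int = 2) -> list[set[str]]:
    """Single-linkage clusters by repeated transitive closure."""
    groups = [{s} for s in set(seqs)]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(naive_distance(x, y) <= max_mismatch
                       for x in groups[i] for y in groups[j]):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return groups


def naive_target_scan(mirna: str, transcript: str) -> list[tuple[int, float]]:
    """Ungapped antiparallel scoring of every transcript offset.

    Returns (t_high, penalty) for each full-length placement; penalties use
    the position-dependent system (core = miRNA positions 2-13, doubled).
    """
    L = len(mirna)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = []
    for t_high in range(L - 1, len(transcript)):
        pen = 0.0
        for i in range(L):
            m, t = mirna[i], transcript[t_high - i]
            if comp[m] == t:
                p = 0.0
            elif (m == "G" and t == "T") or (m == "T" and t == "G"):
                p = 0.5
            else:
                p = 1.0
            if 2 <= i + 1 <= 13:
                p *= 2
            pen += p
        out.append((t_high, pen))
    return out


def naive_ac_pvalue(x: int, y: int, n1: int, n2: int, tail_pad: int = 4000
                    ) -> float:
    """Two-sided Audic-Claverie p-value by direct log-space summation of
    p(k|x) = (n2/n1)^k (x+k)! / (x! k! (1+n2/n1)^(x+k+1))."""
    r = np.log(n2 / n1)
    s = np.log1p(n2 / n1)
    kmax = y + tail_pad + int(4 * (x + y + 10))
    k = np.arange(0, kmax + 1)
    logp = (k * r + gammaln(x + k + 1) - gammaln(x + 1) - gammaln(k + 1)
            - (x + k + 1) * s)
    p = np.exp(logp)
    lower = p[:y + 1].sum()
    upper = p[y:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))
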