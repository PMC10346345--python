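"""Independent brute-force reference implementations used by the tests.

Everything here is coded directly from the defining formulas with plain
Python loops (or closed forms), deliberately avoiding the code paths and
libraries used by the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

# --- time-domain -----------------------------------------------------------


def mad(x) -> float:
    m = sum(x) / len(x)
    return sum(abs(v - m) for v in x) / len(x)


def rms(x) -> float:
    return math.sqrt(sum(v * v for v in x) / len(x))


def variance(x) -> float:
    m = sum(x) / len(x)
    return sum((v - m) ** 2 for v in x) / len(x)


def skewness(x) -> float:
    m = sum(x) / len(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    m3 = sum((v - m) ** 3 for v in x) / len(x)
    return m3 / m2**1.5


def kurtosis(x) -> float:
    m = sum(x) / len(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    m4 = sum((v - m) ** 4 for v in x) / len(x)
    return m4 / m2**2


def aac(x) -> float:
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)) / (len(x) - 1)


def hjorth(x) -> tuple[float, float, float]:
    d1 = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    d2 = [d1[i + 1] - d1[i] for i in range(len(d1) - 1)]
    act = variance(x)
    mob = math.sqrt(variance(d1) / act)
    mob_d = math.sqrt(variance(d2) / variance(d1))
    return act, mob, mob_d / mob


# --- entropies -------------------------------------------------------------


def shannon_entropy(x, n_bins: int = 16) -> float:
    lo, hi = min(x), max(x)
    if hi <= lo:
        return 0.0
    counts = [0] * n_bins
    for v in x:
        b = int((v - lo) / (hi - lo) * n_bins)
        counts[min(b, n_bins - 1)] += 1
    h = 0.0
    for c in counts:
        if c:
            p = c / len(x)
            h -= p * math.log(p)
    return h


def log_entropy(x) -> float:
    return sum(math.log(v * v) for v in x if v != 0.0)


def threshold_entropy(x, eps: float) -> float:
    return float(sum(1 for v in x if abs(v) > eps))


def sure_entropy(x, eps: float) -> float:
    n_small = sum(1 for v in x if abs(v) <= eps)
    return len(x) - n_small + sum(min(v * v, eps * eps) for v in x)


def norm_entropy(x, p: float) -> float:
    return sum(abs(v) ** p for v in x)


# --- Daubechies-2 periodized DWT ------------------------------------------

_S3 = math.sqrt(3.0)
_H = [(1 + _S3) / (4 * math.sqrt(2)), (3 + _S3) / (4 * math.sqrt(2)),
      (3 - _S3) / (4 * math.sqrt(2)), (1 - _S3) / (4 * math.sqrt(2))]
DEC_LO = [_H[3], _H[2], _H[1], _H[0]]
DEC_HI = [-_H[0], _H[1], -_H[2], _H[3]]


def dwt_step(x):
    """One periodized analysis step: (approximation, detail)."""
    n = len(x)
    a = [sum(DEC_LO[m] * x[(2 * k - m + 2) % n] for m in range(4))
         for k in range(n // 2)]
    d = [sum(DEC_HI[m] * x[(2 * k - m + 2) % n] for m in range(4))
         for k in range(n // 2)]
    return a, d


def dwt_detail_energies(x, levels: int):
    """Detail energies d1..dL and approximation energy, zero-padding the
    signal to a multiple of 2**levels first."""
    x = list(x)
    block = 2**levels
    if len(x) % block:
        x = x + [0.0] * (block - len(x) % block)
    energies = []
    for _ in range(levels):
        x, d = dwt_step(x)
        energies.append(sum(v * v for v in d))
    return energies, sum(v * v for v in x)


# --- Mann-Whitney ----------------------------------------------------------


def mannwhitney_u(x, y) -> float:
    """U by exhaustive pair counting (ties count half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mannwhitney_sigma(x, y) -> float:
    """Tie-corrected standard deviation of U."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = sorted(list(x) + list(y))
    tie = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        t = j - i
        tie += t**3 - t
        i = j
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    return math.sqrt(var) if var > 0 else 0.0


# --- classification metrics ------------------------------------------------


def auc_by_pair_counting(y, scores) -> float:
    """P(score_pos > score_neg) with ties counting half."""
    pos = [s for yi, s in zip(y, scores) if yi == 1]
    neg = [s for yi, s in zip(y, scores) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def binary_mcc(tp: int, fn: int, fp: int, tn: int) -> float:
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return num / den if den else 0.0
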