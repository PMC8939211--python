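"""Permutation inference for predictor comparisons.

Benchmark test sets are curated, not random samples, so classical
population-model tests (t-tests, Neyman–Pearson confidence intervals)
rest on assumptions that do not hold.  The Fisher–Pitman permutation
model conditions on the observed data instead: under the null that two
predictors perform identically, the sign of each per-chain paired
difference d_i = a_i - b_i is exchangeable, and the null distribution of
the mean difference is generated by flipping those signs.

The p-value is the proportion of sign arrangements whose mean is at
least (alternative="greater") or at most ("less") the observed mean,
with the observed arrangement counted.  All 2^n arrangements are
enumerated when n <= ``exact_threshold`` (default 16); otherwise ``r``
Monte-Carlo sign vectors are drawn from a seeded generator and
p = (count + 1) / (r + 1), so p >= 1/(r+1).  Arrangements tying the
observed mean within 1e-12 count toward p (conservative).

Statistical significance is reported together with practical
significance: the paired Cohen's d = mean(d) / sd(d) (sample sd, n-1),
binned as negligible (< 0.01), very small (< 0.2), small (< 0.5),
medium (< 0.8), large (< 1.2) or very large (>= 1.2) on |d|.
Comparisons with fewer than ``min_n`` (default 20) valid pairs are not
tested at all and render as a dash.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np

from .metrics import UNDEFINED

__all__ = [
    "EFFECT_BINS",
    "PairedComparison",
    "NotRun",
    "paired_permutation_test",
    "cohens_d_paired",
    "interpret_effect",
    "guarded_test",
]

_TIE_TOL = 1e-12

#: (upper bound on |d|, label); the last bin is open-ended.
EFFECT_BINS: tuple[tuple[float, str], ...] = (
    (0.01, "negligible"),
    (0.2, "very small"),
    (0.5, "small"),
    (0.8, "medium"),
    (1.2, "large"),
    (float("inf"), "very large"),
)


@dataclass
class PairedComparison:
    """Result of one paired predictor comparison on one metric."""

    ids: tuple[str, ...]
    a_values: np.ndarray
    b_values: np.ndarray
    p_value: float
    d: Optional[float]
    interpretation: Optional[str]
    n: int
    method: str  # "exact-enumeration" | "monte-carlo"
    r_permutations: int
    seed: int
    alternative: str
    alpha: float
    significant: bool


@dataclass(frozen=True)
class NotRun:
    """Marker for a comparison skipped by the minimum-sample guard;
    rendered as a dash in reports."""

    n: int
    min_n: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"not run (n={self.n} < {self.min_n})"


def _clean_diffs(a: Sequence[float], b: Sequence[float]) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in paired vectors")
    return a - b


def paired_permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "greater",
    r: int = 9999,
    seed: int = 0,
    exact_threshold: int = 16,
) -> tuple[float, str]:
    """One-sided paired Fisher–Pitman test on the mean difference.

    Returns ``(p_value, method)`` with method ``"exact-enumeration"``
    (n <= exact_threshold) or ``"monte-carlo"`` (r draws, seeded).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = _clean_diffs(a, b)
    n = d.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    observed = d.sum()  # compare sums: same ordering as means
    if n <= exact_threshold:
        # all 2^n sign vectors via the bits of 0..2^n-1
        codes = np.arange(2 ** n, dtype=np.int64)[:, None]
        signs = ((codes >> np.arange(n)) & 1) * 2 - 1
        stats = signs @ d
        if alternative == "greater":
            count = int(np.sum(stats >= observed - _TIE_TOL))
        else:
            count = int(np.sum(stats <= observed + _TIE_TOL))
        return count / (2 ** n), "exact-enumeration"
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(r, n)) * 2 - 1
    stats = signs @ d
    if alternative == "greater":
        count = int(np.sum(stats >= observed - _TIE_TOL))
    else:
        count = int(np.sum(stats <= observed + _TIE_TOL))
    return (count + 1) / (r + 1), "monte-carlo"


def cohens_d_paired(a: Sequence[float], b: Sequence[float]) -> Optional[float]:
    """Paired Cohen's d: mean(a-b) / sd(a-b), sample (n-1) sd.

    sd = 0 with zero mean gives d = 0; sd = 0 with non-zero mean is
    UNDEFINED (infinite standardised effect) and warns.
    """
    d = _clean_diffs(a, b)
    if d.size < 2:
        raise ValueError(f"need at least 2 pairs, got {d.size}")
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0
        warnings.warn("zero-variance differences with non-zero mean: d undefined")
        return UNDEFINED
    return mean / sd


def interpret_effect(d: Optional[float]) -> Optional[str]:
    """Bin |d| into the conventional qualitative effect-size labels."""
    if d is UNDEFINED:
        return UNDEFINED
    if not np.isfinite(d):
        raise ValueError("effect size must be finite")
    mag = abs(d)
    for bound, label in EFFECT_BINS:
        if mag < bound:
            return label
    return EFFECT_BINS[-1][1]  # pragma: no cover - inf bound catches all


def guarded_test(
    pairs: dict[str, tuple[Optional[float], Optional[float]]],
    alternative: str = "greater",
    min_n: int = 20,
    alpha: float = 0.01,
    r: int = 9999,
    seed: int = 0,
    exact_threshold: int = 16,
) -> PairedComparison | NotRun:
    """Drop UNDEFINED pairs, apply the minimum-sample guard, then test.

    ``pairs`` maps chain id -> (value_A, value_B); a pair is dropped if
    either side is UNDEFINED.  With fewer than ``min_n`` retained pairs
    no test is run and a :class:`NotRun` marker is returned.
    """
    kept = [
        (cid, va, vb)
        for cid, (va, vb) in pairs.items()
        if va is not UNDEFINED and vb is not UNDEFINED
    ]
    n = len(kept)
    if n < min_n:
        return NotRun(n=n, min_n=min_n)
    ids = tuple(cid for cid, _, _ in kept)
    a = np.array([va for _, va, _ in kept], dtype=float)
    b = np.array([vb for _, _, vb in kept], dtype=float)
    p, method = paired_permutation_test(
        a, b, alternative=alternative, r=r, seed=seed, exact_threshold=exact_threshold
    )
    d = cohens_d_paired(a, b)
    return PairedComparison(
        ids=ids,
        a_values=a,
        b_values=b,
        p_value=p,
        d=d,
        interpretation=interpret_effect(d),
        n=n,
        method=method,
        r_permutations=r,
        seed=seed,
        alternative=alternative,
        alpha=alpha,
        significant=bool(p < alpha),
    )
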