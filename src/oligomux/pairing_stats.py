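"""Quantification statistics for cytological pairing counts.

These operate on manually scored cell counts: 2x2 contingency tables
(stripe-domain pairing enrichment), tel1-vs-tel2 orientation counts at
metaphase I, and partially-paired configuration class counts across
replicate gonads.

The exact tests are computed by integer summation of point probabilities
(math.comb), so ties at the observed probability are resolved exactly with
no floating-point fuzz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd


def _validate_counts(values, name: str = "count") -> list[int]:
    out = []
    for v in np.asarray(values).ravel():
        f = float(v)
        if f < 0 or f != int(f):
            raise ValueError(f"{name}s must be non-negative integers, got {v!r}")
        out.append(int(f))
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative integers.

    The two-sided p is the point-probability method: the sum, over all tables
    with the observed margins, of hypergeometric point probabilities no
    larger than the observed table's. Computed with exact integer binomial
    coefficients, so the result is exact to float rounding.
    """
    a, b, c, d = _validate_counts(table, "table entr")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    observed = weights[a - lo]
    total = math.comb(n, c1)
    p = Fraction(sum(w for w in weights if w <= observed), total)
    return float(p)


def binom_test_half(k: int, n: int) -> float:
    """Exact two-sided binomial p-value of k successes in n trials at p = 1/2.

    Point-probability method: at p = 1/2 every outcome's probability is
    proportional to C(n, i), so the two-sided p sums C(n, i) over outcomes no
    more probable than the observed one, divided by 2^n — exact integers
    throughout.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must be in 0..n")
    observed = math.comb(n, k)
    num = sum(c for c in (math.comb(n, i) for i in range(n + 1)) if c <= observed)
    return float(min(Fraction(num, 2**n), Fraction(1)))


@dataclass(frozen=True)
class OrientationResult:
    """tel1-paired fraction of metaphase I cells plus exact binomial p vs 0.5."""

    tel1_count: int
    tel2_count: int
    fraction: float
    percent: int            # rounded half-up, as displayed in the field
    p_value: float

    @property
    def n(self) -> int:
        return self.tel1_count + self.tel2_count


def orientation_fraction(tel1_count: int, tel2_count: int) -> OrientationResult:
    """Fraction of cells with tel1 paired, with an exact binomial test vs 1/2.

    Raises if both counts are zero. The percent display rounds half-up to an
    integer.
    """
    (t1,) = _validate_counts([tel1_count])
    (t2,) = _validate_counts([tel2_count])
    n = t1 + t2
    if n == 0:
        raise ValueError("at least one of tel1_count/tel2_count must be positive")
    fraction = t1 / n
    # round-half-up of 100*t1/n in exact integer arithmetic
    percent = (200 * t1 + n) // (2 * n)
    return OrientationResult(t1, t2, fraction, percent, binom_test_half(t1, n))


@dataclass
class ConfigurationFrequencies:
    """Mean +/- SD of per-category cell fractions across replicate gonads."""

    categories: list[str]
    mean: np.ndarray
    sd: np.ndarray
    per_replicate: pd.DataFrame
    single_replicate: bool   # SD undefined with one replicate; reported as 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": self.categories, "mean_fraction": self.mean, "sd": self.sd}
        )


def configuration_frequencies(counts: pd.DataFrame | np.ndarray,
                              categories: Sequence[str] | None = None,
                              ) -> ConfigurationFrequencies:
    """Per-category fraction of cells, averaged across replicates.

    `counts` is replicates x categories (DataFrame columns name the
    categories). Each replicate's fractions sum to 1; mean and sample SD
    (ddof=1) are taken across replicates. A single replicate has no defined
    SD: zeros are reported with `single_replicate` set.
    """
    if isinstance(counts, pd.DataFrame):
        categories = list(counts.columns)
        arr = counts.to_numpy()
    else:
        arr = np.asarray(counts)
        if arr.ndim == 1:
            arr = arr[None, :]
        if categories is None:
            categories = [f"category_{i}" for i in range(arr.shape[1])]
    _validate_counts(arr)
    arr = arr.astype(float)
    totals = arr.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("every replicate must contain at least one cell")
    fractions = arr / totals[:, None]
    single = fractions.shape[0] == 1
    mean = fractions.mean(axis=0)
    sd = np.zeros_like(mean) if single else fractions.std(axis=0, ddof=1)
    per_rep = pd.DataFrame(fractions, columns=list(categories))
    return ConfigurationFrequencies(
        categories=list(categories), mean=mean, sd=sd,
        per_replicate=per_rep, single_replicate=single,
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-corrected p-values (optional; tests are reported uncorrected
    by default, matching per-comparison reporting practice)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
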