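"""Exact rank-sum null distributions ("dice-sum") and signed P-value scores.

Under the null, each matched 9-mer assigns the focal genus a uniform rank in
1..s (s = number of reference genera, 54 by default), independently across
the n matched 9-mers of a reading frame — exactly the distribution of the sum
of n fair s-sided dice.  The closed-form inclusion–exclusion PMF

    P(p, n, s) = s^-n * sum_{k=0}^{floor((p-n)/s)} (-1)^k C(n,k) C(p-s*k-1, n-1)

is provided (and kept exact over rationals for oracle use), but production
tables are built by iterated convolution of the uniform PMF, which is stable
at large n where the alternating sum cancels catastrophically.

The *P-value score* of an observed rank sum is the PMF value at that sum,
negated when the sum falls below the distribution's mode (the low, non-
significant side); downstream reporting uses log10(1/|score|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Integral
from pathlib import Path

import numpy as np

__all__ = [
    "dice_sum_pmf",
    "dice_sum_pmf_exact",
    "PValueTable",
    "SignedPValueScore",
    "build_pvalue_table",
    "pvalue_score",
    "PValueDatabase",
    "build_pvalue_database",
    "log10_inverse",
]


def _check_int(name: str, value) -> int:
    if isinstance(value, bool) or not isinstance(value, Integral):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    return int(value)


def dice_sum_pmf(p, n, s) -> float:
    """Probability that n fair s-sided dice sum to p (closed form).

    Uses exact integer combinatorics before the final division, so the result
    is correctly rounded for moderate n; for large n prefer the convolution
    tables (:class:`PValueDatabase`).
    """
    p = _check_int("p", p)
    n = _check_int("n", n)
    s = _check_int("s", s)
    if n < 1 or s < 2:
        raise ValueError("require n >= 1 and s >= 2")
    if p < n or p > n * s:
        return 0.0
    k_max = (p - n) // s
    total = 0
    for k in range(k_max + 1):
        term = math.comb(n, k) * math.comb(p - s * k - 1, n - 1)
        total += -term if k % 2 else term
    return total / s**n


def dice_sum_pmf_exact(p, n, s) -> Fraction:
    """Exact-rational variant of :func:`dice_sum_pmf` (small-n oracle)."""
    p = _check_int("p", p)
    n = _check_int("n", n)
    s = _check_int("s", s)
    if n < 1 or s < 2:
        raise ValueError("require n >= 1 and s >= 2")
    if p < n or p > n * s:
        return Fraction(0)
    total = 0
    for k in range((p - n) // s + 1):
        term = math.comb(n, k) * math.comb(p - s * k - 1, n - 1)
        total += -term if k % 2 else term
    return Fraction(total, s**n)


@dataclass
class PValueTable:
    """Exact PMF of the rank sum of ``n`` matched 9-mers over ``s`` genera.

    ``pmf[i]`` is the probability of rank sum ``n + i``; the support is
    ``[n, n*s]``.  ``mode_sum`` is the rank sum with maximal probability
    (smallest such sum if tied), the boundary of the sign convention.
    """

    n: int
    s: int
    pmf: np.ndarray

    @property
    def support(self) -> range:
        return range(self.n, self.n * self.s + 1)

    @property
    def mode_sum(self) -> int:
        return self.n + int(np.argmax(self.pmf))

    def prob(self, rank_sum: int) -> float:
        rank_sum = _check_int("rank_sum", rank_sum)
        if rank_sum < self.n or rank_sum > self.n * self.s:
            raise ValueError(
                f"rank sum {rank_sum} outside support [{self.n}, {self.n * self.s}]"
            )
        return float(self.pmf[rank_sum - self.n])


def build_pvalue_table(n, s: int = 54, _prev: PValueTable | None = None) -> PValueTable:
    """Build the rank-sum PMF for ``n`` matches by iterated convolution.

    ``_prev`` may hold the table for ``n - 1`` to extend incrementally.
    """
    n = _check_int("n", n)
    s = _check_int("s", s)
    if n < 1 or s < 2:
        raise ValueError("require n >= 1 and s >= 2")
    uniform = np.full(s, 1.0 / s)
    if _prev is not None and _prev.s == s and _prev.n == n - 1:
        pmf = np.convolve(_prev.pmf, uniform)
    else:
        pmf = uniform
        for _ in range(n - 1):
            pmf = np.convolve(pmf, uniform)
    return PValueTable(n, s, pmf)


@dataclass(frozen=True)
class SignedPValueScore:
    """PMF magnitude with the below-mode/at-or-above-mode sign convention."""

    magnitude: float
    sign: int

    @property
    def value(self) -> float:
        return self.sign * self.magnitude


def pvalue_score(rank_sum, table: PValueTable) -> SignedPValueScore:
    """Signed P-value score of an observed rank sum.

    The magnitude is the null probability of the observed sum; the sign is
    −1 when the sum falls below the mode (the statistically non-significant,
    low-rank side) and +1 otherwise.
    """
    rank_sum = _check_int("rank_sum", rank_sum)
    magnitude = table.prob(rank_sum)
    sign = -1 if rank_sum < table.mode_sum else 1
    return SignedPValueScore(magnitude, sign)


def log10_inverse(score: float) -> float:
    """log10 of the inverse magnitude of a signed P-value score."""
    return math.log10(1.0 / abs(score))


class PValueDatabase:
    """Lazily built, cached collection of rank-sum tables for n in [n_min, n_max].

    The default range 2..625 yields 624 tables.  Tables are built on demand
    (extending incrementally from the largest table already built) and can be
    saved to / loaded from a TSV cache with one row per (n, rank sum, pmf).
    """

    def __init__(self, s: int = 54, n_min: int = 2, n_max: int = 625):
        if n_min > n_max:
            raise ValueError("n_min must be <= n_max")
        if n_min < 1:
            raise ValueError("n_min must be >= 1")
        self.s = _check_int("s", s)
        self.n_min = _check_int("n_min", n_min)
        self.n_max = _check_int("n_max", n_max)
        self._tables: dict[int, PValueTable] = {}

    def table(self, n) -> PValueTable:
        """Return the table for ``n`` matches, building it if needed."""
        n = _check_int("n", n)
        if n < 1:
            raise ValueError("n must be >= 1")
        if n in self._tables:
            return self._tables[n]
        built = [m for m in self._tables if m < n]
        current_n = max(built) if built else 0
        current = self._tables.get(current_n)
        for m in range(current_n + 1, n + 1):
            current = build_pvalue_table(m, self.s, _prev=current)
            if self.n_min <= m <= self.n_max or m == n:
                self._tables[m] = current
        return self._tables[n]

    def build_all(self) -> "PValueDatabase":
        self.table(self.n_max)
        for n in range(self.n_min, self.n_max + 1):
            if n not in self._tables:  # pragma: no cover - table() fills the range
                self.table(n)
        return self

    def __len__(self) -> int:
        """Number of tables in the configured range (builds them if absent)."""
        self.build_all()
        return sum(1 for n in self._tables if self.n_min <= n <= self.n_max)

    def save(self, path: str | Path) -> None:
        """Write all tables in range as TSV rows (n, rank_sum, pmf)."""
        self.build_all()
        with open(path, "w") as fh:
            fh.write(f"# s={self.s}\nn\trank_sum\tpmf\n")
            for n in range(self.n_min, self.n_max + 1):
                t = self._tables[n]
                for p, prob in zip(t.support, t.pmf):
                    fh.write(f"{n}\t{p}\t{prob:.17g}\n")

    @classmethod
    def load(cls, path: str | Path) -> "PValueDatabase":
        rows: dict[int, list[tuple[int, float]]] = {}
        s = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if line[1:].strip().startswith("s="):
                        s = int(line.split("=", 1)[1])
                    continue
                if not line or line.startswith("n\t"):
                    continue
                n_str, p_str, prob_str = line.split("\t")
                rows.setdefault(int(n_str), []).append((int(p_str), float(prob_str)))
        if s is None or not rows:
            raise ValueError(f"{path}: not a P-value table cache")
        db = cls(s=s, n_min=min(rows), n_max=max(rows))
        for n, entries in rows.items():
            entries.sort()
            pmf = np.array([prob for _, prob in entries])
            db._tables[n] = PValueTable(n, s, pmf)
        return db


def build_pvalue_database(
    n_min: int = 2, n_max: int = 625, s: int = 54
) -> PValueDatabase:
    """Fully built table collection (default: the 624 tables for 2–625 matches)."""
    return PValueDatabase(s=s, n_min=n_min, n_max=n_max).build_all()
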