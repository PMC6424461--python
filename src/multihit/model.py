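"""Closed-form probabilities of the multi-combination multi-hit model.

The model: carcinogenesis occurs when any one of ``k`` alternative
combinations of ``h`` specific carcinogenic mutations (hits) is completed
by the accumulating somatic mutations.  With ``G`` equally likely mutable
loci and ``m`` accumulated somatic mutations,

* ``P_h(m)`` — probability that one given h-hit combination is complete
  after m mutations (inclusion-exclusion over the h loci),
* ``P_k(m) = 1 - (1 - P_h(m))^k`` — probability that at least one of the
  k combinations is complete,
* ``P(m) = P_k(m) - P_k(m-1)`` — probability that the m-th mutation is
  the completing hit.

``P_h`` is of order ``(m/G)^h`` (down to ~1e-40 for h = 8 at exome scale),
so the alternating inclusion-exclusion sum cancels catastrophically in
double precision.  Evaluation strategy, validated against a 60-digit
arbitrary-precision reference:

* when P_h is appreciable (>= ~1e-5, judged by the cheap surrogate
  ``(1 - (1-1/G)^m)^h``) the direct alternating sum is reliable
  (absolute rounding error ~1e-12) and is used — it is *exact* in the
  small-G regime covered by the enumeration oracle;
* otherwise the sum is rearranged as a power series in 1/G,

      P_h(m) = sum_{j=h}^{m} (-1)^(j-h) [m]_j / G^j * h! S(j, h) / j!

  with ``[m]_j`` the falling factorial and ``S`` Stirling numbers of the
  second kind (the j < h layers of the binomial expansion cancel
  identically, which is precisely the mass lost to rounding in the direct
  sum).  Successive terms shrink like ~m*h/G, so there is no
  cancellation; run to j = m the series is exact, and truncation keeps
  the relative error well below 1e-9 whenever m*h/G < 0.5.  Outside both
  regimes (never reached at genome or oracle scale) the evaluation falls
  back to the arbitrary-precision sum.

``P_k`` is evaluated as ``-expm1(k * log1p(-P_h))`` so that the only
quantity that must be well scaled is ``k * P_h``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import comb, factorial
from typing import Iterable

import mpmath
import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "ProbabilityCurve",
    "prob_single_combination",
    "prob_any_combination",
    "prob_increment",
    "evaluate_curve",
    "brute_force_reference",
    "exact_inclusion_exclusion",
    "estimate_combination_count",
    "default_genome_target_count",
]

#: Above this value of the stable surrogate for P_h the direct
#: inclusion-exclusion sum carries at least ~7 accurate digits.
_DIRECT_SUM_THRESHOLD = 1e-5

#: Enumeration cap for the brute-force oracle (G**m sequences).
_ENUMERATION_CAP = 2_000_000


def default_genome_target_count() -> float:
    """Number of somatic mutations that can become fixed in the exome.

    3.25e9 bp haploid genome x 2 (diploid) x 1.5% exome x 1.1 fixable
    mutations per locus (accounting for synonymous changes and the excess
    of non-synonymous calls in tumor exomes) = 1.0725e8.
    """
    return 3.25e9 * 2 * 1.1 * 1.5 / 100


def estimate_combination_count(
    loci_per_gene: int, copies: int, genes: int, h: int
) -> float:
    """Back-of-envelope count of possible carcinogenic h-hit combinations.

    With ``loci_per_gene`` function-altering loci per gene, ``copies``
    genome copies and ``genes`` cancer-relevant genes, any h of the
    ``loci_per_gene * copies * genes`` loci form a candidate combination,
    giving ``(loci_per_gene * copies * genes)**h`` ordered choices.
    E.g. (1000, 2, 50, h=2) -> 1e10 and (1000, 2, 50, h=8) -> 1e40.
    """
    if min(loci_per_gene, copies, genes, h) < 1:
        raise ValueError("all arguments must be >= 1")
    return float(loci_per_gene * copies * genes) ** h


@dataclass(frozen=True)
class ModelParams:
    """One multi-combination multi-hit model: (G, h, k).

    Parameters
    ----------
    G : float
        Number of all possible somatic mutations that can become fixed
        (default exome scale ~1.0725e8).
    h : int
        Number of hits required for carcinogenesis, ``1 <= h <= G``.
    k : float
        Number of alternative carcinogenic h-hit combinations, ``>= 1``.
        Real-valued: the fitted search grid spans 1e3–1e48.
    """

    G: float
    h: int
    k: float

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError(f"G must be >= 1, got {self.G}")
        if not (1 <= self.h <= self.G):
            raise ValueError(f"h must satisfy 1 <= h <= G, got h={self.h}, G={self.G}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


@dataclass(frozen=True)
class ProbabilityCurve:
    """Model probabilities tabulated over m = 0..m_max.

    ``p_h[m]`` and ``p_k[m]`` are the single- and any-combination hit
    probabilities; ``p_increment[m] = p_k[m] - p_k[m-1]`` is the
    per-mutation carcinogenesis probability P(m) (``p_increment[0] = 0``).
    """

    params: ModelParams
    m_max: int
    p_h: np.ndarray = field(repr=False)
    p_k: np.ndarray = field(repr=False)
    p_increment: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as a DataFrame with columns m, p_h, p_k, p_increment."""
        return pd.DataFrame(
            {
                "m": np.arange(self.m_max + 1),
                "p_h": self.p_h,
                "p_k": self.p_k,
                "p_increment": self.p_increment,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@lru_cache(maxsize=32)
def _stirling2_row(h: int, j_max: int) -> tuple[float, ...]:
    """Stirling numbers of the second kind S(j, h) for j = h..j_max."""
    # S(j, h) = h S(j-1, h) + S(j-1, h-1), built over exact integers;
    # prev holds S(j, hh-1) for j = hh-1..j_max
    prev = [1] + [0] * j_max  # S(j, 0) for j = 0..j_max
    for hh in range(1, h + 1):
        val = 1  # S(hh, hh)
        row = [val]
        for idx in range(j_max - hh):  # j = hh+1 .. j_max
            val = hh * val + prev[idx + 1]
            row.append(val)
        prev = row
    return tuple(float(v) for v in prev)


def _ph_series(G: float, h: int, m: np.ndarray, j_extra: int = 40) -> np.ndarray:
    """Cancellation-free 1/G power series for tiny P_h (terms decay ~mh/G)."""
    m = np.asarray(m, dtype=float)
    j_max = h + j_extra
    stirling = _stirling2_row(h, j_max)
    h_fact = float(factorial(h))
    # falling factorial [m]_h / G^h
    ff = np.ones_like(m)
    for t in range(h):
        ff *= (m - t) / G
    coef = 1.0  # h! S(h, h) / h!
    acc = ff * coef
    sign = 1.0
    fact_j = h_fact
    for j in range(h + 1, j_max + 1):
        ff = ff * (m - (j - 1)) / G
        fact_j *= j
        coef = h_fact * stirling[j - h] / fact_j
        sign = -sign
        term = sign * ff * coef
        acc = acc + term
        if np.all(np.abs(term) <= 1e-16 * np.abs(acc)):
            break
    return np.clip(acc, 0.0, 1.0)


def _ph_vector(G: float, h: int, m: np.ndarray) -> np.ndarray:
    """P_h over an integer array of mutation counts, stable at all scales."""
    m = np.asarray(m, dtype=float)
    one_minus = -np.expm1(m * np.log1p(-1.0 / G))  # 1 - (1-1/G)^m in [0, 1]
    if h == 1:
        ph = one_minus.copy()  # exact closed form for a single hit
        ph[m < 1] = 0.0
        return ph
    surrogate = np.where(one_minus > 0, one_minus, 0.0) ** h
    ph = np.zeros_like(m)
    direct_mask = surrogate >= _DIRECT_SUM_THRESHOLD
    if np.any(direct_mask):
        # direct alternating sum: carries >= ~7 digits when P_h >= 1e-5
        md = m[direct_mask]
        acc = np.zeros_like(md)
        for i in range(h + 1):
            ratio = (G - i) / G
            if ratio <= 0.0:
                term = np.where(md > 0, 0.0, 1.0)
            else:
                term = np.exp(md * np.log(ratio))
            acc += (-1.0) ** i * comb(h, i) * term
        ph[direct_mask] = np.clip(acc, 0.0, 1.0)
    series_mask = (~direct_mask) & (m >= h)
    if np.any(series_mask):
        ms = m[series_mask]
        if ms.size and np.max(ms) * h / G < 0.5:
            ph[series_mask] = _ph_series(G, h, ms)
        else:
            # pathological middle ground; defer to arbitrary precision
            ph[series_mask] = np.array(
                [float(exact_inclusion_exclusion(G, h, int(x))) for x in ms]
            )
    ph[m < h] = 0.0
    return ph


def _pk_from_ph(ph: np.ndarray, k: float) -> np.ndarray:
    """1 - (1 - P_h)^k via expm1/log1p; k*P_h is the well-scaled product."""
    with np.errstate(divide="ignore"):
        log1p_m = np.log1p(-ph)
    # -inf arises only when ph == 1.0, where P_k is exactly 1
    t = np.where(np.isfinite(log1p_m), k * log1p_m, -np.inf)
    return -np.expm1(t)


def prob_single_combination(params: ModelParams, m: int) -> float:
    """P_h(m): probability one given h-hit combination is complete.

    Exactly 0 for m < h.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    return float(_ph_vector(params.G, params.h, np.array([m]))[0])


def prob_any_combination(params: ModelParams, m: int) -> float:
    """P_k(m): probability at least one of the k combinations is complete."""
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    ph = _ph_vector(params.G, params.h, np.array([m]))
    return float(_pk_from_ph(ph, params.k)[0])


def prob_increment(params: ModelParams, m: int) -> float:
    """P(m) = P_k(m) - P_k(m-1): the m-th mutation completes a combination.

    ``P_k(0) = 0`` by convention (no mutations, no hits), so
    ``prob_increment(params, 1) == prob_any_combination(params, 1)``.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    ph = _ph_vector(params.G, params.h, np.array([m - 1, m]))
    pk = _pk_from_ph(ph, params.k)
    return float(max(pk[1] - pk[0], 0.0))


def evaluate_curve(params: ModelParams, m_max: int) -> ProbabilityCurve:
    """Tabulate P_h, P_k and P over m = 0..m_max.

    P_h is computed once per (G, h); sweeping k on a fixed (G, h) reuses
    it, so evaluating a full mantissa-decade k grid at m_max = 5000 is a
    handful of vector operations.
    """
    if m_max < 1:
        raise ValueError(f"m_max must be >= 1, got {m_max}")
    m = np.arange(m_max + 1)
    ph = _ph_vector(params.G, params.h, m)
    pk = _pk_from_ph(ph, params.k)
    pk = np.maximum.accumulate(pk)  # guard monotonicity against rounding
    inc = np.diff(pk, prepend=0.0)
    inc[0] = 0.0
    return ProbabilityCurve(params=params, m_max=m_max, p_h=ph, p_k=pk, p_increment=inc)


def brute_force_reference(
    G: int, hit_loci: Iterable[int], m: int
) -> Fraction:
    """Exact hit probability by exhaustive enumeration of all G^m sequences.

    Counts the mutation sequences (ordered, with replacement, over G
    equally likely loci) in which every locus in ``hit_loci`` appears at
    least once, and returns the exact fraction.  Independent test oracle
    for :func:`prob_single_combination`; refuses above the enumeration cap.
    """
    loci = frozenset(hit_loci)
    if not 1 <= G <= 8 or m > 8 or m < 0:
        raise ValueError("enumeration oracle supports 1 <= G <= 8, 0 <= m <= 8")
    if any(not 0 <= x < G for x in loci):
        raise ValueError("hit_loci must be locus indices in [0, G)")
    if G**m > _ENUMERATION_CAP:
        raise ValueError(f"G^m = {G**m} exceeds enumeration cap {_ENUMERATION_CAP}")
    target = 0
    for x in loci:
        target |= 1 << x
    hits = 0
    masks = [1 << x for x in range(G)]
    for seq in itertools.product(masks, repeat=m):
        covered = 0
        for b in seq:
            covered |= b
        if covered & target == target:
            hits += 1
    return Fraction(hits, G**m)


def exact_inclusion_exclusion(G: float, h: int, m: int, dps: int = 60) -> mpmath.mpf:
    """P_h(m) by the alternating inclusion-exclusion sum, ``dps`` digits.

    Arbitrary-precision reference for the production evaluation.  The
    alternating sum cancels roughly ``-log10(P_h)`` digits (up to ~70 at
    genome scale), so the working precision is raised by the estimated
    loss to keep ``dps`` significant digits in the *result*.
    """
    if m < h:
        return mpmath.mpf(0)
    # leading-order magnitude [m]_h / G^h estimates the cancellation depth
    import math

    log10_lead = sum(math.log10(max(m - t, 1)) for t in range(h)) - h * math.log10(G)
    lost = max(0, int(-log10_lead) + 1)
    with mpmath.workdps(dps + lost):
        Gm = mpmath.mpf(G)
        total = mpmath.mpf(0)
        for i in range(h + 1):
            term = mpmath.binomial(h, i) * ((Gm - i) / Gm) ** m
            total += (-1) ** i * term
        result = +total
    with mpmath.workdps(dps):
        return +result
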