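"""Linkage-disequilibrium statistics from direct gamete counting.

With phased haplotypes the two-locus gamete frequencies are observed, not
estimated, so D, D' and r² follow directly:

    D    = p_AB - p_A * p_B
    D'   = |D| / D_max,   D_max = min(p_A p_B, (1-p_A)(1-p_B))   for D < 0
                          D_max = min(p_A(1-p_B), (1-p_A) p_B)   for D > 0
    r²   = D² / (p_A (1-p_A) p_B (1-p_B))

All frequencies are taken over the cohort's 2N chromosomes. Monomorphic
loci raise an explicit error rather than propagating NaN.

The four-gamete test is the classic recombination detector: observing all
four gametes (00, 01, 10, 11) at a pair of biallelic loci implies at least
one crossover or recurrent mutation between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MonomorphicSiteError, ValidationError
from .haplotypes import HaplotypeMatrix


@dataclass(frozen=True)
class LDResult:
    p_a: float
    p_b: float
    p_ab: float
    d: float
    d_prime: float
    r2: float
    n_gametes: int  # distinct two-locus gametes observed (1-4)


@dataclass(frozen=True)
class FourGameteResult:
    all_four: bool
    gamete_counts: dict[str, int]  # keys "00", "01", "10", "11"


def _gamete_counts(hm: HaplotypeMatrix, i: int, j: int) -> dict[str, int]:
    gam = hm.gametes()
    a = gam[:, i].astype(int)
    b = gam[:, j].astype(int)
    return {
        "00": int(np.sum((a == 0) & (b == 0))),
        "01": int(np.sum((a == 0) & (b == 1))),
        "10": int(np.sum((a == 1) & (b == 0))),
        "11": int(np.sum((a == 1) & (b == 1))),
    }


def _check_pair(hm: HaplotypeMatrix, i: int, j: int) -> None:
    L = hm.n_sites
    if not (0 <= i < L and 0 <= j < L):
        raise ValidationError(f"site index out of range (L={L})")
    if i == j:
        raise ValidationError("LD statistics need two distinct loci")


def ld_pair(hm: HaplotypeMatrix, i: int, j: int) -> LDResult:
    """D, D' and r² between panel sites ``i`` and ``j``.

    Both loci must be polymorphic in the cohort; a monomorphic locus raises
    :class:`MonomorphicSiteError` naming the site.
    """
    _check_pair(hm, i, j)
    counts = _gamete_counts(hm, i, j)
    n = sum(counts.values())
    if n == 0:
        raise ValidationError("no haplotypes in matrix")
    p_a = (counts["10"] + counts["11"]) / n
    p_b = (counts["01"] + counts["11"]) / n
    for p, site in ((p_a, i), (p_b, j)):
        if p == 0.0 or p == 1.0:
            raise MonomorphicSiteError(
                f"site {hm.panel[site].variant_id} is monomorphic (p={p:g})"
            )
    p_ab = counts["11"] / n
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = 1.0  # irrelevant: D = 0 -> D' = 0
    d_prime = abs(d) / d_max if d != 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    n_gametes = sum(1 for c in counts.values() if c > 0)
    return LDResult(p_a=p_a, p_b=p_b, p_ab=p_ab, d=d, d_prime=d_prime,
                    r2=r2, n_gametes=n_gametes)


def ld_matrix(hm: HaplotypeMatrix, stat: str = "r2") -> pd.DataFrame:
    """Symmetric L×L matrix of ``stat`` in {"r2", "d_prime"}.

    Rows/columns at monomorphic sites are masked with NaN (explicitly
    flagged, not zero-filled); the diagonal is 1 for polymorphic sites.
    """
    if stat not in ("r2", "d_prime"):
        raise ValidationError(f"unknown LD statistic {stat!r}")
    freqs = hm.allele_frequencies()
    poly = (freqs > 0) & (freqs < 1)
    if poly.sum() < 2:
        raise ValidationError("LD matrix needs at least 2 polymorphic sites")
    L = hm.n_sites
    out = np.full((L, L), np.nan)
    for i in range(L):
        if poly[i]:
            out[i, i] = 1.0
        for j in range(i + 1, L):
            if poly[i] and poly[j]:
                res = ld_pair(hm, i, j)
                out[i, j] = out[j, i] = getattr(res, stat)
    ids = hm.panel.variant_ids
    return pd.DataFrame(out, index=ids, columns=ids)


def four_gamete(hm: HaplotypeMatrix, i: int, j: int,
                min_count: int = 1) -> FourGameteResult:
    """Four-gamete test at a pair of sites.

    ``min_count`` (default 1: singleton gametes count) guards against
    genotyping error by requiring each gamete to be seen that many times.
    """
    _check_pair(hm, i, j)
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    counts = _gamete_counts(hm, i, j)
    all_four = all(c >= min_count for c in counts.values())
    return FourGameteResult(all_four=all_four, gamete_counts=counts)
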