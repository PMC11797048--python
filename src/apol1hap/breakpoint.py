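"""Single-crossover breakpoint localization and origin-hypothesis scoring.

A putative recombinant haplotype ``r`` is explained as parent A left of a
crossover and parent B right of it. Only *informative* sites — where the
two candidate parents differ — constrain the crossover; the inferred
breakpoint is the open genomic interval between the last informative site
matching parent A and the first informative site matching parent B. For the
M1-G2 haplotype the two flanking informative sites are the M1 variant
(chr22:36265628) and the G2 deletion (chr22:36265995), giving the 367 bp
window within which the crossover must lie.

The model is a single crossover: haplotypes requiring two or more
crossovers (under the mismatch tolerance) are reported infeasible, not
fitted. A site where ``r`` matches neither parent counts as one mismatch
regardless of the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .panel import VariantPanel
from .recombmap import RecombMap

FEASIBLE = "feasible"
INFEASIBLE = "infeasible"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BreakpointInterval:
    status: str  # feasible | infeasible | ambiguous
    left_pos: Optional[int] = None   # last informative site from parent A
    right_pos: Optional[int] = None  # first informative site from parent B
    parent_a_id: Optional[int] = None
    parent_b_id: Optional[int] = None
    mismatches: Optional[int] = None

    @property
    def width(self) -> Optional[int]:
        if self.left_pos is None or self.right_pos is None:
            return None
        return self.right_pos - self.left_pos


@dataclass(frozen=True)
class OriginScore:
    hypothesis: str  # "independent_mutation" | "recombination"
    events: int      # mutations + crossovers required
    detail: str


def _as_matrix(hs, L: int, name: str) -> np.ndarray:
    if len(hs) == 0:
        raise ValidationError(f"{name} parent set is empty")
    mat = np.asarray([np.asarray(h, dtype=np.uint8) for h in hs])
    if mat.shape[1] != L:
        raise ValidationError(f"{name} haplotype length disagrees with panel")
    return mat


def infer_breakpoint(
    r,
    set_a: Sequence,
    set_b: Sequence,
    panel: VariantPanel,
    max_mismatch: int = 0,
) -> BreakpointInterval:
    """Localize the single crossover explaining ``r`` from parents in
    ``set_a`` (left segment) and ``set_b`` (right segment).

    Every parent pair and every crossover placement between consecutive
    informative sites is scored by its mismatch count (sites explained by
    neither side of the split). Among placements within ``max_mismatch``,
    the winner has minimal mismatches, then minimal interval width, then the
    lowest (a, b) parent indices. Returns:

    - ``ambiguous`` when ``r`` is identical to a parent, or is explained by
      a single parent alone (no crossover needed);
    - ``infeasible`` when no pair/placement fits within ``max_mismatch``.
    """
    r = np.asarray(r, dtype=np.uint8)
    L = len(panel)
    if len(r) != L:
        raise ValidationError("recombinant length disagrees with panel")
    A = _as_matrix(set_a, L, "set_a")
    B = _as_matrix(set_b, L, "set_b")
    if any((r == a).all() for a in A) or any((r == b).all() for b in B):
        return BreakpointInterval(status=AMBIGUOUS)

    pos = panel.positions
    best: Optional[tuple[int, int, int, int, int, int]] = None
    parental_fit = False  # some pair explained r without an interior split
    for ai, a in enumerate(A):
        for bi, b in enumerate(B):
            inf = np.nonzero(a != b)[0]
            base = int(np.count_nonzero((a == b) & (r != a)))
            mis_a = (r[inf] != a[inf]).astype(int)  # violations left of split
            mis_b = (r[inf] != b[inf]).astype(int)  # violations right of split
            # mism(k) = base + sum(mis_a[:k]) + sum(mis_b[k:]), k = 0..len(inf)
            cum_a = np.concatenate([[0], np.cumsum(mis_a)])
            cum_b = np.concatenate([np.cumsum(mis_b[::-1])[::-1], [0]])
            total = base + cum_a + cum_b
            for k in range(len(inf) + 1):
                m = int(total[k])
                if m > max_mismatch:
                    continue
                if k == 0 or k == len(inf):
                    parental_fit = True
                    continue
                left = int(pos[inf[k - 1]])
                right = int(pos[inf[k]])
                cand = (m, right - left, ai, bi, left, right)
                if best is None or cand < best:
                    best = cand
    if best is not None:
        m, _, ai, bi, left, right = best
        return BreakpointInterval(status=FEASIBLE, left_pos=left,
                                  right_pos=right, parent_a_id=ai,
                                  parent_b_id=bi, mismatches=m)
    if parental_fit:
        return BreakpointInterval(status=AMBIGUOUS)
    return BreakpointInterval(status=INFEASIBLE)


def score_origin(
    r,
    set_g2: Sequence,
    set_m1g0: Sequence,
    panel: VariantPanel,
) -> tuple[OriginScore, OriginScore]:
    """Parsimony comparison of the two origins of an M1-G2 haplotype.

    ``independent_mutation``: M1 arose again on the closest G2 haplotype —
    one M1 mutation plus every other background difference that would have
    to recur, i.e. 1 + min Hamming(r, h in set_g2) excluding the M1 site.

    ``recombination``: one crossover joining an M1-G0 haplotype (left) to a
    G2 haplotype (right) — 1 + the residual mismatches of the best
    single-crossover decomposition.
    """
    r = np.asarray(r, dtype=np.uint8)
    m1_idx = panel.index_of_role("M1")
    g2_idx = panel.index_of_role("G2_del")
    if not r[m1_idx] or not r[g2_idx]:
        raise ValidationError("score_origin expects a haplotype carrying both "
                              "the M1 and G2 tag alleles")
    G2 = _as_matrix(set_g2, len(panel), "set_g2")
    keep = np.arange(len(panel)) != m1_idx
    hammings = [(int(np.count_nonzero(r[keep] != h[keep])), hi)
                for hi, h in enumerate(G2)]
    best_ham, best_h = min(hammings)
    indep = OriginScore(
        hypothesis="independent_mutation",
        events=1 + best_ham,
        detail=(f"M1 mutation + {best_ham} recurring background difference(s) "
                f"vs G2 haplotype {best_h}"),
    )
    bp = infer_breakpoint(r, set_m1g0, set_g2, panel, max_mismatch=len(panel))
    if bp.status == FEASIBLE:
        events = 1 + int(bp.mismatches)
        detail = (f"crossover in ({bp.left_pos}, {bp.right_pos}) from parents "
                  f"(a={bp.parent_a_id}, b={bp.parent_b_id}) + "
                  f"{bp.mismatches} residual mutation(s)")
    else:
        # no interior split even at full tolerance: r is parental up to point
        # mutations; one crossover is still the minimal recombination story
        events = 1
        detail = f"no interior split required (status {bp.status})"
    recomb = OriginScore(hypothesis="recombination", events=events,
                         detail=detail)
    return indep, recomb


def map_rate_in_interval(rmap: RecombMap, chrom: str, start: int,
                         end: int) -> Optional[float]:
    """Overlap-weighted mean recombination rate (cM/Mb) over [start, end).

    Returns None (undefined-rate status) when the map does not overlap the
    query; raises on an inverted interval.
    """
    if end <= start:
        raise ValidationError(f"inverted or empty interval [{start}, {end})")
    weight = 0.0
    acc = 0.0
    for iv in rmap.intervals:
        if iv.chrom != chrom:
            continue
        ov = min(end, iv.end) - max(start, iv.start)
        if ov > 0:
            acc += iv.rate * ov
            weight += ov
    if weight == 0:
        return None
    return acc / weight
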