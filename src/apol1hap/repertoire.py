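"""Haplotype repertoire operations: classify, tally, exclusivity, clustering.

The repertoire of a cohort is the set of *unique* haplotypes observed among
its 2N phased chromosomes, each with a count and a classification:

risk class
    G2 when the haplotype carries the G2 deletion allele; G1 when it
    carries both G1 tag SNPs (and not G2); G1_partial when it carries
    exactly one of the two G1 SNPs (flagged — the two SNPs are expected to
    co-occur); otherwise G0.
M1 flag
    whether the protective p.N264K allele is present.
background
    the EMR/EIK/KIK coding background spelled by the alleles at amino-acid
    positions 150/228/255: reference (0,0,0) = EMR, (0,1,1) = EIK,
    (1,1,1) = KIK, anything else = OTHER.

Haplotypes simultaneously carrying G1 and G2 tags are classified G2 but
flagged as conflicting rather than silently accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import to_tree

from .errors import ConfigurationError, ValidationError
from .haplotypes import HaplotypeMatrix
from .panel import ROLE_TAGS, VariantPanel
from .presence import ALT_OBSERVED, REF_ONLY, PresenceProfile

logger = logging.getLogger(__name__)

RISK_CLASSES = ("G0", "G1", "G2", "G1_partial")
BACKGROUNDS = ("EMR", "EIK", "KIK", "OTHER")

_BACKGROUND_CODE = {(0, 0, 0): "EMR", (0, 1, 1): "EIK", (1, 1, 1): "KIK"}


@dataclass(frozen=True)
class HaplotypeClass:
    risk: str
    m1: bool
    background: str
    conflict: bool = False  # G1 and G2 tags simultaneously present

    def label(self) -> str:
        m1 = "M1-" if self.m1 else ""
        return f"{m1}{self.risk}/{self.background}"


@dataclass
class HaplotypeRecord:
    """A unique haplotype with its cohort count and classification."""

    alleles: np.ndarray
    count: int
    classification: HaplotypeClass
    carrier_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.count < 1:
            raise ValidationError("record count must be >= 1")

    @property
    def allele_string(self) -> str:
        return "".join(map(str, self.alleles.tolist()))


def _role_indices(panel: VariantPanel) -> dict[str, int]:
    missing = [r for r in ROLE_TAGS if not panel.has_role(r)]
    if missing:
        raise ConfigurationError(
            f"panel lacks required role tags for classification: {missing}"
        )
    return {r: panel.index_of_role(r) for r in ROLE_TAGS}


def classify_haplotype(h, panel: VariantPanel) -> HaplotypeClass:
    """Classify one binary haplotype by its tag-variant alleles."""
    h = np.asarray(h, dtype=np.uint8)
    if len(h) != len(panel):
        raise ValidationError("haplotype length disagrees with panel")
    idx = _role_indices(panel)
    g1a, g1b = int(h[idx["G1_snp1"]]), int(h[idx["G1_snp2"]])
    g2 = int(h[idx["G2_del"]])
    conflict = bool(g2 and (g1a or g1b))
    if g2:
        risk = "G2"
    elif g1a and g1b:
        risk = "G1"
    elif g1a or g1b:
        risk = "G1_partial"
        logger.warning("haplotype carries exactly one G1 tag SNP (G1_partial)")
    else:
        risk = "G0"
    bg = _BACKGROUND_CODE.get(
        (int(h[idx["bg150"]]), int(h[idx["bg228"]]), int(h[idx["bg255"]])), "OTHER"
    )
    return HaplotypeClass(risk=risk, m1=bool(h[idx["M1"]]), background=bg,
                          conflict=conflict)


def tally_unique(hm: HaplotypeMatrix) -> list[HaplotypeRecord]:
    """Count the unique haplotypes among the cohort's 2N chromosomes.

    Records come back in a deterministic order: descending count, then
    lexicographic allele string. Counts conserve the total number of
    haplotypes entering the tally.
    """
    if hm.n_samples == 0:
        raise ValidationError("cannot tally an empty cohort")
    gam = hm.gametes()
    uniq, inverse, counts = np.unique(gam, axis=0, return_inverse=True,
                                      return_counts=True)
    carriers: list[set[str]] = [set() for _ in range(len(uniq))]
    for row, u in enumerate(inverse.ravel()):
        carriers[u].add(hm.sample_ids[row // 2])
    order = sorted(
        range(len(uniq)),
        key=lambda i: (-int(counts[i]), tuple(uniq[i].tolist())),
    )
    return [
        HaplotypeRecord(
            alleles=uniq[i],
            count=int(counts[i]),
            classification=classify_haplotype(uniq[i], hm.panel),
            carrier_samples=sorted(carriers[i]),
        )
        for i in order
    ]


def exclusive_variants(
    records: Sequence[HaplotypeRecord],
    panel: VariantPanel,
    group_a: Callable[[HaplotypeClass], bool],
    group_b: Callable[[HaplotypeClass], bool],
    min_fraction_a: float = 1.0,
    count_weighted: bool = True,
    annotation_classes: Optional[Sequence[str]] = None,
) -> set[str]:
    """Variants carried by (a fraction of) group A and by no group-B haplotype.

    With the default ``min_fraction_a = 1.0`` a variant must be alternate on
    every group-A haplotype (count-weighted by default) and reference on all
    of group B — the strict reading of "exclusive". ``annotation_classes``
    restricts candidates (e.g. to intronic sites, as when hunting the
    M1-lineage intronic markers).
    """
    if not 0.0 < min_fraction_a <= 1.0:
        raise ValidationError("min_fraction_a must be in (0, 1]")
    a_recs = [r for r in records if group_a(r.classification)]
    b_recs = [r for r in records if group_b(r.classification)]
    if not a_recs:
        raise ValidationError("group_a predicate selected no haplotypes")
    if not b_recs:
        raise ValidationError("group_b predicate selected no haplotypes")
    a_mat = np.stack([r.alleles for r in a_recs])
    b_mat = np.stack([r.alleles for r in b_recs])
    if count_weighted:
        w = np.array([r.count for r in a_recs], dtype=float)
        frac_a = (a_mat * w[:, None]).sum(axis=0) / w.sum()
    else:
        frac_a = a_mat.mean(axis=0)
    in_b = b_mat.any(axis=0)
    ok_class = np.ones(len(panel), dtype=bool)
    if annotation_classes is not None:
        wanted = set(annotation_classes)
        ok_class = np.array([v.annotation_class in wanted for v in panel])
    # tolerance so min_fraction_a=1.0 survives float weighting round-off
    hit = (frac_a >= min_fraction_a - 1e-12) & ~in_b & ok_class
    return {panel[i].variant_id for i in np.nonzero(hit)[0]}


def jaccard_distance(h1, h2) -> float:
    """1 - |shared alt sites| / |union of alt sites|; 0 for two all-reference
    haplotypes (empty union — identical vectors)."""
    a = np.asarray(h1, dtype=bool)
    b = np.asarray(h2, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("haplotypes must be 1-D vectors of equal length")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    shared = int(np.logical_and(a, b).sum())
    return 1.0 - shared / union


@dataclass
class ClusterTree:
    """Agglomerative tree over unique haplotypes on the Jaccard scale."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) linkage encoding
    records: list[HaplotypeRecord]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.records)

    def leaf_labels(self) -> list[str]:
        return [
            f"h{i}_{r.classification.label()}_n{r.count}"
            for i, r in enumerate(self.records)
        ]

    def first_merge_partners(self, leaf: int) -> set[int]:
        """Leaves of the sibling cluster at the given leaf's first merge.

        For the recombinant-placement check: the recombinant's first merge
        partner set tells which haplotypes the tree considers closest.
        """
        n = self.n_leaves
        members = {i: {i} for i in range(n)}
        for step, (x, y, _, _) in enumerate(self.linkage_matrix):
            xi, yi = int(x), int(y)
            mx, my = members[xi], members[yi]
            if leaf in mx:
                return set(my)
            if leaf in my:
                return set(mx)
            members[n + step] = mx | my
        raise ValidationError(f"leaf {leaf} not in tree")  # pragma: no cover

    def to_newick(self) -> str:
        labels = self.leaf_labels()
        root = to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            kids = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({kids}):{length:.6g}"

        kids = ",".join(fmt(c, root.dist) for c in (root.left, root.right))
        return f"({kids});"


def _agglomerate(dm: np.ndarray, sizes: np.ndarray, method: str) -> np.ndarray:
    """Agglomerative clustering with explicit tie-breaking.

    Lance-Williams updates for single/complete/average linkage; ``sizes``
    weights the average-linkage update (unit sizes reproduce ordinary
    UPGMA). Ties in the minimum inter-cluster distance are broken by the
    lowest (i, j) cluster-index pair, so the tree is bit-reproducible for a
    fixed input order. Returns a scipy-format linkage matrix.
    """
    n = len(dm)
    d = dm.astype(float).copy()
    size = {i: float(sizes[i]) for i in range(n)}
    active = list(range(n))  # cluster ids, ascending
    cluster_of = {i: i for i in range(n)}  # id -> row in d
    Z = np.zeros((n - 1, 4))
    nleaves = {i: 1 for i in range(n)}
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                dij = d[cluster_of[i], cluster_of[j]]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        dij, i, j = best
        ri, rj = cluster_of[i], cluster_of[j]
        new_id = n + step
        for k in active:
            if k in (i, j):
                continue
            rk = cluster_of[k]
            if method == "single":
                dnew = min(d[rk, ri], d[rk, rj])
            elif method == "complete":
                dnew = max(d[rk, ri], d[rk, rj])
            else:  # average, size-weighted
                si, sj = size[i], size[j]
                dnew = (si * d[rk, ri] + sj * d[rk, rj]) / (si + sj)
            d[rk, ri] = d[ri, rk] = dnew
        Z[step] = (i, j, dij, nleaves[i] + nleaves[j])
        nleaves[new_id] = nleaves[i] + nleaves[j]
        size[new_id] = size[i] + size[j]
        cluster_of[new_id] = ri  # reuse row i for the merged cluster
        active.remove(i)
        active.remove(j)
        active.append(new_id)
        active.sort()
    return Z


def cluster_haplotypes(
    records: Sequence[HaplotypeRecord],
    method: str = "complete",
    count_weighted: bool = False,
) -> ClusterTree:
    """Hierarchically cluster unique haplotypes by Jaccard distance.

    By default every unique haplotype enters with unit weight (one leaf per
    unique haplotype, as in a row-per-haplotype repertoire display);
    ``count_weighted=True`` weights average-linkage merges by cohort counts
    instead (single/complete linkage are weight-free). Deterministic under
    a fixed record order: distance ties merge the lowest index pair.
    """
    if method not in ("single", "average", "complete"):
        raise ValidationError(f"unsupported linkage method {method!r}")
    if len(records) < 2:
        raise ValidationError("clustering needs at least 2 unique haplotypes")
    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = jaccard_distance(records[i].alleles,
                                                   records[j].alleles)
    sizes = (np.array([r.count for r in records], dtype=float)
             if count_weighted else np.ones(n))
    Z = _agglomerate(dm, sizes, method)
    return ClusterTree(linkage_matrix=Z, records=list(records), method=method)


@dataclass(frozen=True)
class PresenceMatch:
    """One candidate (haplotype pair or single haplotype) scored against a
    presence profile."""

    record_indices: tuple[int, ...]
    classes: tuple[HaplotypeClass, ...]
    informative_sites: int
    conflicts: int

    @property
    def consistent_sites(self) -> int:
        return self.informative_sites - self.conflicts


def match_presence(
    profile: PresenceProfile,
    records: Sequence[HaplotypeRecord],
    mode: str = "pairs",
) -> list[PresenceMatch]:
    """Rank repertoire haplotypes by compatibility with an unphased profile.

    A candidate is a pair of unique haplotypes (``mode="pairs"``, the
    diploid reading of a "combined" presence profile) or a single haplotype
    (``mode="homozygous"``). Scoring uses only informative sites (those with
    any coverage): an ``alt_observed`` site must be alternate on at least
    one candidate haplotype, a ``ref_only`` site must be reference on all of
    them; each violation is one conflict. Candidates are ranked by fewest
    conflicts, then most consistent sites, then candidate order.
    """
    if mode not in ("pairs", "homozygous"):
        raise ValidationError(f"unknown mode {mode!r}")
    if not records:
        raise ValidationError("no candidate haplotypes")
    L = len(profile.panel)
    if any(len(r.alleles) != L for r in records):
        raise ValidationError("records and profile cover different panels")
    alt_sites = np.array([c == ALT_OBSERVED for c in profile.calls])
    ref_sites = np.array([c == REF_ONLY for c in profile.calls])
    informative = int(alt_sites.sum() + ref_sites.sum())

    def score(mat: np.ndarray) -> int:
        any_alt = mat.any(axis=0)
        conflicts = int((alt_sites & ~any_alt).sum())
        conflicts += int((ref_sites & any_alt).sum())
        return conflicts

    out: list[PresenceMatch] = []
    if mode == "homozygous":
        for i, r in enumerate(records):
            out.append(PresenceMatch(
                record_indices=(i,), classes=(r.classification,),
                informative_sites=informative,
                conflicts=score(r.alleles[None, :]),
            ))
    else:
        for i in range(len(records)):
            for j in range(i, len(records)):
                mat = np.stack([records[i].alleles, records[j].alleles])
                out.append(PresenceMatch(
                    record_indices=(i, j),
                    classes=(records[i].classification,
                             records[j].classification),
                    informative_sites=informative,
                    conflicts=score(mat),
                ))
    out.sort(key=lambda m: (m.conflicts, -m.consistent_sites, m.record_indices))
    return out
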