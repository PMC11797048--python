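"""Classification, tallying, exclusivity, Jaccard clustering, presence match."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

import apol1hap as ah
from apol1hap.errors import ConfigurationError, ValidationError

from conftest import make_matrix


def tagged_panel():
    """Seven consecutive sites, one per role tag (classification testbed)."""
    roles = ["G1_snp1", "G1_snp2", "G2_del", "M1", "bg150", "bg228", "bg255"]
    return ah.VariantPanel([
        ah.PanelVariant(f"t{i}", "chr22", 100 + 10 * i, "C", "T", "exonic", r)
        for i, r in enumerate(roles)
    ])


def expected_class(bits):
    """Independent truth-table oracle for classify_haplotype."""
    g1a, g1b, g2, m1, b150, b228, b255 = bits
    if g2:
        risk = "G2"
    elif g1a and g1b:
        risk = "G1"
    elif g1a or g1b:
        risk = "G1_partial"
    else:
        risk = "G0"
    bg = {(0, 0, 0): "EMR", (0, 1, 1): "EIK", (1, 1, 1): "KIK"}.get(
        (b150, b228, b255), "OTHER")
    return risk, bool(m1), bg, bool(g2 and (g1a or g1b))


def test_classify_matches_truth_table_over_all_128_settings():
    panel = tagged_panel()
    for bits in itertools.product((0, 1), repeat=7):
        got = ah.classify_haplotype(np.array(bits), panel)
        risk, m1, bg, conflict = expected_class(bits)
        assert (got.risk, got.m1, got.background, got.conflict) == \
            (risk, m1, bg, conflict), bits


@pytest.mark.parametrize("bits, label", [
    ((0, 0, 0, 0, 0, 0, 0), "G0/EMR"),
    ((0, 0, 1, 1, 1, 1, 1), "M1-G2/KIK"),
    ((1, 1, 0, 0, 0, 1, 1), "G1/EIK"),
], ids=["all-reference", "m1-g2-kik", "g1-eik"])
def test_classification_labels(bits, label):
    got = ah.classify_haplotype(np.array(bits), tagged_panel())
    assert got.label() == label


def test_classify_requires_role_tags(mini_panel):
    with pytest.raises(ConfigurationError, match="role"):
        ah.classify_haplotype(np.zeros(3, dtype=int), mini_panel)


def test_tally_conserves_counts_and_orders(panel, founders):
    f = {x.label: x.haplotype for x in founders}
    rows = [(f["G0_EIK"], f["G0_EIK"])] * 6 + [(f["G0_EIK"], f["G2_EIK"])] * 3
    hm = make_matrix(panel, [(a.tolist(), b.tolist()) for a, b in rows])
    recs = ah.tally_unique(hm)
    assert sum(r.count for r in recs) == hm.n_haplotypes == 18
    assert [r.count for r in recs] == sorted((r.count for r in recs),
                                             reverse=True)
    assert recs[0].count == 15  # G0_EIK on 6 hom + 3 het samples
    assert recs[1].classification.risk == "G2"
    assert recs[1].carrier_samples == ["S6", "S7", "S8"]


def test_tally_all_reference_cohort(panel):
    hm = make_matrix(panel, [(np.zeros(28), np.zeros(28))] * 10)
    recs = ah.tally_unique(hm)
    assert len(recs) == 1 and recs[0].count == 20
    c = recs[0].classification
    assert (c.risk, c.m1, c.background) == ("G0", False, "EMR")


def test_tally_matches_simulated_multiset(cohort):
    hm, truth = cohort
    recs = ah.tally_unique(hm)
    by_string = {r.allele_string: r.count for r in recs}
    # oracle: count founder labels in the simulator's own truth
    pool = {f.label: f.haplotype for f in truth.config.founders}
    pool[ah.RECOMBINANT_LABEL] = truth.recombinant_haplotype
    labels, counts = np.unique(truth.founder_labels, return_counts=True)
    for label, count in zip(labels, counts):
        key = "".join(map(str, pool[label].tolist()))
        assert by_string[key] == count


# ---------------------------------------------------------------- exclusivity

def _rec(alleles, count=1):
    panel = tagged_panel()
    h = np.zeros(7, dtype=np.uint8)
    h[:len(alleles)] = alleles
    return ah.HaplotypeRecord(alleles=np.asarray(alleles, dtype=np.uint8),
                              count=count,
                              classification=ah.classify_haplotype(h, panel))


def test_one_discriminating_site(mini_panel):
    a = _rec([1, 1, 0])  # classifies G1 (both tag SNPs of the testbed panel)
    b = _rec([1, 0, 0])  # classifies G1_partial
    out = ah.exclusive_variants(
        [a, b], mini_panel,
        group_a=lambda c: c.risk == "G1",
        group_b=lambda c: c.risk == "G1_partial",
    )
    assert out == {"v2"}


def test_identical_groups_give_empty_set(mini_panel):
    a = _rec([1, 1, 0])
    out = ah.exclusive_variants(
        [a], mini_panel,
        group_a=lambda c: True,
        group_b=lambda c: True,
    )
    assert out == set()


def brute_force_exclusive(records, panel, in_a, in_b, min_fraction_a):
    a = [r for r in records if in_a(r)]
    b = [r for r in records if in_b(r)]
    out = set()
    for site in range(len(panel)):
        wa = sum(r.count for r in a if r.alleles[site])
        ta = sum(r.count for r in a)
        if wa / ta >= min_fraction_a - 1e-12 and \
                all(not r.alleles[site] for r in b):
            out.add(panel[site].variant_id)
    return out


@pytest.mark.parametrize("min_fraction", [1.0, 0.75, 0.5])
def test_exclusive_matches_brute_force(panel, min_fraction):
    rng = np.random.default_rng(3)
    recs = []
    for i in range(12):
        h = rng.integers(0, 2, size=28).astype(np.uint8)
        recs.append(ah.HaplotypeRecord(
            alleles=h, count=int(rng.integers(1, 6)),
            classification=ah.classify_haplotype(h, panel)))
    in_a = lambda r: r.classification.m1
    in_b = lambda r: not r.classification.m1
    if not any(in_a(r) for r in recs) or not any(in_b(r) for r in recs):
        pytest.skip("degenerate draw")  # pragma: no cover
    got = ah.exclusive_variants(recs, panel,
                                group_a=lambda c: c.m1,
                                group_b=lambda c: not c.m1,
                                min_fraction_a=min_fraction)
    want = brute_force_exclusive(recs, panel, in_a, in_b, min_fraction)
    assert got == want


def test_exclusive_anti_monotone_in_min_fraction(records, panel):
    sets = [
        ah.exclusive_variants(records, panel,
                              group_a=lambda c: c.m1,
                              group_b=lambda c: not c.m1 and c.risk in ("G1", "G2"),
                              min_fraction_a=f)
        for f in (0.4, 0.7, 1.0)
    ]
    assert sets[2] <= sets[1] <= sets[0]


def test_exclusive_empty_group_is_an_error(records, panel):
    with pytest.raises(ValidationError, match="group_b"):
        ah.exclusive_variants(records, panel,
                              group_a=lambda c: True,
                              group_b=lambda c: False)


# ------------------------------------------------------------------- jaccard

@pytest.mark.parametrize("h1, h2, d", [
    ([1, 1, 0, 0], [1, 1, 0, 0], 0.0),
    ([1, 1, 0, 0], [1, 0, 1, 0], 2 / 3),
    ([0, 0, 0, 0], [0, 0, 0, 0], 0.0),  # empty-union convention
    ([1, 0], [0, 1], 1.0),
], ids=["identical", "one-shared-of-three", "both-all-ref", "disjoint"])
def test_jaccard_examples(h1, h2, d):
    assert ah.jaccard_distance(h1, h2) == pytest.approx(d)


def test_jaccard_length_mismatch():
    with pytest.raises(ValidationError):
        ah.jaccard_distance([1, 0], [1, 0, 1])


@settings(derandomize=True, max_examples=200)
@given(st.integers(2, 12).flatmap(
    lambda L: st.tuples(*[st.lists(st.integers(0, 1), min_size=L, max_size=L)
                          for _ in range(3)])))
def test_jaccard_is_a_metric(triple):
    """Symmetry, identity and the triangle inequality on random vectors."""
    a, b, c = triple
    dab = ah.jaccard_distance(a, b)
    assert dab == ah.jaccard_distance(b, a)
    assert 0.0 <= dab <= 1.0
    assert ah.jaccard_distance(a, a) == 0.0
    assert dab <= ah.jaccard_distance(a, c) + ah.jaccard_distance(c, b) + 1e-12


# ---------------------------------------------------------------- clustering

def test_forced_first_merge(mini_panel):
    a = _rec([1, 1, 0])
    b = _rec([1, 1, 1])   # d(a,b) = 1/3
    c = _rec([0, 0, 1])   # d(a,c) = 1, d(b,c) = 2/3
    tree = ah.cluster_haplotypes([a, b, c])
    assert set(tree.linkage_matrix[0, :2].astype(int)) == {0, 1}
    assert tree.first_merge_partners(0) == {1}


def test_identical_leaves_merge_at_height_zero():
    a = _rec([1, 0, 1])
    b = _rec([1, 0, 1])
    c = _rec([0, 1, 0])
    tree = ah.cluster_haplotypes([a, b, c])
    assert tree.linkage_matrix[0, 2] == 0.0
    assert set(tree.linkage_matrix[0, :2].astype(int)) == {0, 1}


@pytest.mark.parametrize("method", ["single", "complete", "average"])
def test_agglomerator_agrees_with_scipy(panel, records, method):
    """Unit-weight linkage cross-checked against scipy.cluster.hierarchy."""
    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = ah.jaccard_distance(records[i].alleles,
                                                      records[j].alleles)
    ours = ah.cluster_haplotypes(records, method=method)
    ref = scipy_linkage(squareform(dm, checks=False), method=method)
    assert np.allclose(np.sort(ours.linkage_matrix[:, 2]),
                       np.sort(ref[:, 2]), atol=1e-12)


def test_merge_heights_monotone(records):
    for method in ("single", "complete", "average"):
        tree = ah.cluster_haplotypes(records, method=method)
        heights = tree.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


def test_cluster_requires_two_leaves():
    with pytest.raises(ValidationError):
        ah.cluster_haplotypes([_rec([1, 0, 0])])


def test_newick_has_all_leaves(records):
    tree = ah.cluster_haplotypes(records)
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for label in tree.leaf_labels():
        assert label in nwk


# ------------------------------------------------------------ presence match

def test_perfect_match_ranks_first(panel, founders):
    f5 = founders[4].haplotype  # M1-G0/KIK
    hm = make_matrix(panel, [(x.haplotype, x.haplotype) for x in founders])
    recs = ah.tally_unique(hm)
    prof = ah.presence_from_counts(panel, f5 * 3, (1 - f5) * 3)
    matches = ah.match_presence(prof, recs, mode="homozygous")
    best = matches[0]
    assert best.conflicts == 0
    assert best.classes[0].label() == "M1-G0/KIK"
    assert best.informative_sites == 28


def test_all_no_data_profile_ties_everything(panel, records):
    prof = ah.presence_from_counts(panel, np.zeros(28, int), np.zeros(28, int))
    matches = ah.match_presence(prof, records)
    assert {m.informative_sites for m in matches} == {0}
    assert {m.conflicts for m in matches} == {0}


def test_degraded_m1_carrier_recovers_true_class(panel, founders):
    """High-coverage degradation of an M1-G0/KIK het carrier: the top-ranked
    pair contains the (G0, m1, KIK) class."""
    f = {x.label: x.haplotype for x in founders}
    hm = make_matrix(panel, [
        (f["M1G0_KIK"], f["G0_EIK"]),
        (f["G0_EIK"], f["G0_EIK"]),
        (f["G2_EIK"], f["G1_EIK"]),
    ])
    recs = ah.tally_unique(hm)
    prof = ah.degrade_to_presence(hm, "S0", mean_depth=50, seed=11)
    matches = ah.match_presence(prof, recs, mode="pairs")
    best = matches[0]
    assert best.conflicts == 0
    assert "M1-G0/KIK" in {c.label() for c in best.classes}
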