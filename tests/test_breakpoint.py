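"""Single-crossover breakpoint localization and origin parsimony."""

import numpy as np
import pytest

import apol1hap as ah
from apol1hap.errors import ValidationError


def plain_panel(positions):
    return ah.VariantPanel([
        ah.PanelVariant(f"p{i}", "chr22", int(p), "C", "T", "intronic")
        for i, p in enumerate(positions)
    ])


def oracle_breakpoint(r, set_a, set_b, positions, max_mismatch):
    """Exhaustive oracle: every parent pair x every crossover placement."""
    r = np.asarray(r)
    best = None
    parental = False
    for ai, a in enumerate(set_a):
        for bi, b in enumerate(set_b):
            a, b = np.asarray(a), np.asarray(b)
            inf = [s for s in range(len(r)) if a[s] != b[s]]
            for k in range(len(inf) + 1):
                m = sum(1 for s in range(len(r))
                        if a[s] == b[s] and r[s] != a[s])
                m += sum(1 for s in inf[:k] if r[s] != a[s])
                m += sum(1 for s in inf[k:] if r[s] != b[s])
                if m > max_mismatch:
                    continue
                if k == 0 or k == len(inf):
                    parental = True
                    continue
                left, right = positions[inf[k - 1]], positions[inf[k]]
                cand = (m, right - left, ai, bi, left, right)
                if best is None or cand < best:
                    best = cand
    if best:
        return ("feasible",) + best
    return ("ambiguous",) if parental else ("infeasible",)


def test_worked_example_six_sites():
    """a=(1,1,0,0,0,0), b=(0,0,0,1,1,1), r=(1,1,0,1,1,1): the crossover is
    bracketed by positions 200 and 400 (site 300 is uninformative)."""
    panel = plain_panel([100, 200, 300, 400, 500, 600])
    a = [1, 1, 0, 0, 0, 0]
    b = [0, 0, 0, 1, 1, 1]
    r = [1, 1, 0, 1, 1, 1]
    bp = ah.infer_breakpoint(r, [a], [b], panel)
    assert bp.status == ah.FEASIBLE
    assert (bp.left_pos, bp.right_pos, bp.width) == (200, 400, 200)
    assert bp.mismatches == 0


def test_parental_haplotype_is_ambiguous():
    panel = plain_panel([100, 200, 300])
    a = [1, 1, 0]
    bp = ah.infer_breakpoint(a, [a], [[0, 0, 1]], panel)
    assert bp.status == ah.AMBIGUOUS
    assert bp.width is None


def test_double_crossover_is_infeasible():
    panel = plain_panel([100, 200, 300, 400])
    a = [1, 1, 1, 1]
    b = [0, 0, 0, 0]
    r = [1, 0, 1, 0]  # needs >= 2 crossovers
    bp = ah.infer_breakpoint(r, [a], [b], panel)
    assert bp.status == ah.INFEASIBLE
    # with tolerance 1 a single crossover plus one mutation explains it
    bp2 = ah.infer_breakpoint(r, [a], [b], panel, max_mismatch=1)
    assert bp2.status == ah.FEASIBLE and bp2.mismatches == 1


def test_empty_parent_set_is_an_error():
    panel = plain_panel([100, 200])
    with pytest.raises(ValidationError, match="set_a"):
        ah.infer_breakpoint([1, 0], [], [[0, 1]], panel)


@pytest.mark.parametrize("trial", range(60))
def test_matches_exhaustive_oracle_on_random_instances(trial):
    rng = np.random.default_rng(1000 + trial)
    L = int(rng.integers(3, 13))
    positions = np.cumsum(rng.integers(1, 100, size=L)) + 50
    panel = plain_panel(positions)
    na, nb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
    A = rng.integers(0, 2, size=(na, L))
    B = rng.integers(0, 2, size=(nb, L))
    r = rng.integers(0, 2, size=L)
    if any((r == a).all() for a in A) or any((r == b).all() for b in B):
        return  # precondition: r must not be parental (covered elsewhere)
    mm = int(rng.integers(0, 3))
    got = ah.infer_breakpoint(r, A, B, panel, max_mismatch=mm)
    want = oracle_breakpoint(r, A, B, positions, mm)
    assert got.status == want[0]
    if want[0] == "feasible":
        m, width, ai, bi, left, right = want[1:]
        assert (got.mismatches, got.width, got.parent_a_id, got.parent_b_id,
                got.left_pos, got.right_pos) == (m, width, ai, bi, left, right)


def test_reversal_symmetry():
    """Reversing site order and swapping parent sets mirrors the interval."""
    rng = np.random.default_rng(77)
    positions = [100, 180, 260, 400, 520, 700]
    panel = plain_panel(positions)
    rev_panel = plain_panel([1000 - p for p in reversed(positions)])
    for _ in range(40):
        A = rng.integers(0, 2, size=(3, 6))
        B = rng.integers(0, 2, size=(3, 6))
        r = rng.integers(0, 2, size=6)
        if any((r == x).all() for x in np.vstack([A, B])):
            continue
        fwd = ah.infer_breakpoint(r, A, B, panel)
        rev = ah.infer_breakpoint(r[::-1], B[:, ::-1], A[:, ::-1], rev_panel)
        assert fwd.status == rev.status
        if fwd.status == ah.FEASIBLE:
            assert rev.width == fwd.width
            assert rev.left_pos == 1000 - fwd.right_pos
            assert rev.right_pos == 1000 - fwd.left_pos


def test_synthetic_scenario_recovers_367bp_window(cohort, panel):
    hm, truth = cohort
    recs = ah.tally_unique(hm)
    m1g0 = [r.alleles for r in recs
            if r.classification.m1 and r.classification.risk != "G2"]
    g2 = [r.alleles for r in recs
          if not r.classification.m1 and r.classification.risk == "G2"]
    rec = next(r for r in recs
               if r.classification.m1 and r.classification.risk == "G2")
    bp = ah.infer_breakpoint(rec.alleles, m1g0, g2, panel)
    assert bp.status == ah.FEASIBLE
    assert (bp.left_pos, bp.right_pos) == (36265628, 36265995)
    assert bp.width == 367
    assert bp.left_pos < truth.crossover_pos < bp.right_pos


# ------------------------------------------------------------- origin scores

def role_panel(positions_roles):
    return ah.VariantPanel([
        ah.PanelVariant(f"q{i}", "chr22", pos, "C", "T", "intronic", role)
        for i, (pos, role) in enumerate(positions_roles)
    ])


FULL_ROLES = [(100, "bg150"), (110, "bg228"), (120, "bg255"),
              (200, "none"), (210, "none"), (220, "none"),
              (300, "M1"), (400, "G1_snp1"), (410, "G1_snp2"),
              (500, "G2_del")]


def test_forced_tie_between_hypotheses():
    """A G2 haplotype differing from r only at the M1 site ties 1 vs 1."""
    panel = role_panel(FULL_ROLES)
    g2 = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 1], dtype=np.uint8)
    r = g2.copy()
    r[6] = 1  # add M1
    m1g0 = np.array([0, 0, 0, 0, 0, 0, 1, 0, 0, 0], dtype=np.uint8)
    indep, recomb = ah.score_origin(r, [g2], [m1g0], panel)
    assert indep.events == 1
    assert recomb.events == 1


def test_three_discriminating_sites_favor_recombination():
    """Parents differing at exactly the three marker sites + M1: recurrent
    mutation needs 4 events, one crossover needs 1."""
    panel = role_panel(FULL_ROLES)
    g2 = np.array([0, 1, 1, 0, 0, 0, 0, 0, 0, 1], dtype=np.uint8)
    m1g0 = np.array([0, 1, 1, 1, 1, 1, 1, 0, 0, 0], dtype=np.uint8)
    r = np.array([0, 1, 1, 1, 1, 1, 1, 0, 0, 1], dtype=np.uint8)
    indep, recomb = ah.score_origin(r, [g2], [m1g0], panel)
    assert indep.events == 4
    assert recomb.events == 1


def test_default_scenario_origin_scores(cohort, panel):
    """Realistic founders: recombination needs 1 event, recurrent mutation
    needs one per lineage difference — and whenever the breakpoint is
    feasible at zero tolerance the recombination score is exactly 1."""
    hm, _ = cohort
    recs = ah.tally_unique(hm)
    m1g0 = [r.alleles for r in recs
            if r.classification.m1 and r.classification.risk != "G2"]
    g2 = [r.alleles for r in recs
          if not r.classification.m1 and r.classification.risk == "G2"]
    rec = next(r for r in recs
               if r.classification.m1 and r.classification.risk == "G2")
    indep, recomb = ah.score_origin(rec.alleles, g2, m1g0, panel)
    assert recomb.events == 1
    # hamming oracle, M1 site excluded
    m1 = panel.index_of_role("M1")
    keep = np.arange(len(panel)) != m1
    want = 1 + min(int((rec.alleles[keep] != h[keep]).sum()) for h in g2)
    assert indep.events == want
    assert indep.events > recomb.events


def test_score_origin_requires_m1_and_g2():
    panel = role_panel(FULL_ROLES)
    r = np.zeros(10, dtype=np.uint8)
    with pytest.raises(ValidationError, match="M1 and G2"):
        ah.score_origin(r, [np.ones(10, dtype=np.uint8)],
                        [np.ones(10, dtype=np.uint8)], panel)
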