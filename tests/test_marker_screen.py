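"""Discovery-screen behavior against independent brute-force oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from radsexscreen import (
    Sex,
    SexLabels,
    SimConfig,
    SnpCandidate,
    TagMatrix,
    TagState,
    call_presence,
    classify_heterogamety,
    exact_2x3_p,
    fisher_exact_2x2,
    screen_exclusive_tags,
    select_top_k,
    simulate_population,
    snp_sex_association,
)
from conftest import make_labels


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def fisher_oracle(table) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration with exact rationals:
    at the observed margins, sum the hypergeometric point masses of every
    table whose mass does not exceed the observed table's."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    if total == 0:
        return Fraction(1)
    obs = weights[a]
    return Fraction(sum(w for w in weights.values() if w <= obs), total)


def column_scan_oracle(tags: TagMatrix, labels: SexLabels):
    """Exhaustive per-column scan for strictly sex-exclusive tags."""
    f_cols = [j for j, i in enumerate(tags.individual_ids)
              if labels.sex_by_id.get(i) is Sex.FEMALE]
    m_cols = [j for j, i in enumerate(tags.individual_ids)
              if labels.sex_by_id.get(i) is Sex.MALE]
    hits = []
    for i, tag in enumerate(tags.tag_ids):
        row = tags.state[i]
        if all(row[j] == TagState.PRESENT for j in m_cols) and \
                not any(row[j] == TagState.PRESENT for j in f_cols):
            hits.append((tag, Sex.MALE))
        if all(row[j] == TagState.PRESENT for j in f_cols) and \
                not any(row[j] == TagState.PRESENT for j in m_cols):
            hits.append((tag, Sex.FEMALE))
    return sorted(hits)


# ---------------------------------------------------------------------------
# Presence calling
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("depth,expected", [
    (5, TagState.PRESENT),
    (3, TagState.PRESENT),
    (1, TagState.MISSING),
    (0, TagState.ABSENT),
])
def test_call_presence_thresholds(depth, expected):
    tags = TagMatrix(["t1"], ["a"],
                     np.array([[int(TagState.MISSING)]]), np.array([[depth]]))
    assert call_presence(tags, min_depth=3).state[0, 0] == expected


def test_call_presence_requires_depth():
    tags = TagMatrix(["t1"], ["a"], np.array([[int(TagState.PRESENT)]]))
    with pytest.raises(ValueError, match="pre-called"):
        call_presence(tags)


# ---------------------------------------------------------------------------
# Exclusive-tag screen
# ---------------------------------------------------------------------------


def _tag_matrix(rows, n_f=10, n_m=10):
    ids = [f"F{i+1}" for i in range(n_f)] + [f"M{i+1}" for i in range(n_m)]
    return TagMatrix([f"tag{i+1}" for i in range(len(rows))], ids,
                     np.array(rows, dtype=np.int8))


def test_shared_tag_is_not_a_candidate():
    tags = _tag_matrix([[int(TagState.PRESENT)] * 20])
    assert screen_exclusive_tags(tags, make_labels(10, 10)) == []


def test_strict_male_exclusive_tag():
    row = [int(TagState.ABSENT)] * 10 + [int(TagState.PRESENT)] * 10
    cands = screen_exclusive_tags(_tag_matrix([row]), make_labels(10, 10))
    assert len(cands) == 1
    c = cands[0]
    assert c.specificity_sex is Sex.MALE
    assert c.n_present_target == 10 and c.n_absent_other == 10


def test_missing_tolerance_controls_candidacy():
    row = [int(TagState.ABSENT)] * 10 + \
          [int(TagState.MISSING)] + [int(TagState.PRESENT)] * 9
    tags = _tag_matrix([row])
    labels = make_labels(10, 10)
    assert screen_exclusive_tags(tags, labels) == []
    assert len(screen_exclusive_tags(tags, labels, max_missing_target=1)) == 1


def test_screen_matches_column_scan_oracle_on_simulation():
    cfg = SimConfig(n_female=10, n_male=10, n_tags=1000,
                    n_sexlinked_tags_male=5, n_sexlinked_tags_female=3,
                    n_loci=1, n_sexlinked_loci=0, missing_rate=0.0, r=0.0,
                    seed=7)
    tags, _, labels, truth = simulate_population(cfg)
    got = sorted((c.tag_id, c.specificity_sex)
                 for c in screen_exclusive_tags(tags, labels))
    assert got == column_scan_oracle(tags, labels)
    assert [t for t, _ in got] == sorted(
        truth.male_exclusive_tags + truth.female_exclusive_tags)


def test_screen_is_label_symmetric():
    cfg = SimConfig(n_tags=200, seed=13, missing_rate=0.02)
    tags, geno, labels, _ = simulate_population(cfg)
    flipped = SexLabels({
        i: (Sex.MALE if s is Sex.FEMALE else Sex.FEMALE)
        for i, s in labels.sex_by_id.items()
    })
    orig = screen_exclusive_tags(tags, labels)
    swap = screen_exclusive_tags(tags, flipped)
    mirror = {Sex.MALE: Sex.FEMALE, Sex.FEMALE: Sex.MALE}
    assert [(c.tag_id, mirror[c.specificity_sex]) for c in orig] == \
        [(c.tag_id, c.specificity_sex) for c in swap]
    # and the association arm swaps ZW <-> XY calls with identical p-values
    a = snp_sex_association(geno, labels)
    b = snp_sex_association(geno, flipped)
    het_mirror = {"ZW": "XY", "XY": "ZW", "inconclusive": "inconclusive"}
    by_locus_b = {c.locus_id: c for c in b}
    assert set(by_locus_b) == {c.locus_id for c in a}
    for c in a:
        mirrored = by_locus_b[c.locus_id]
        # p-values agree up to float round-off of the transposed table
        assert mirrored.p_value == pytest.approx(c.p_value, rel=1e-12)
        assert mirrored.heterogamety_call == het_mirror[c.heterogamety_call]


# ---------------------------------------------------------------------------
# Fisher exact association
# ---------------------------------------------------------------------------


def test_fisher_examples_from_enumeration():
    # 10 all-het females vs 10 all-hom males: p = 2 / C(20,10)
    assert fisher_exact_2x2([[10, 0], [0, 10]]) == \
        pytest.approx(2 / math.comb(20, 10), rel=1e-12)
    # (3 het, 1 hom) vs (1 het, 3 hom): two-sided sum = 34/70
    assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70, rel=1e-12)


@given(st.tuples(st.integers(0, 30), st.integers(0, 30),
                 st.integers(0, 30), st.integers(0, 30)))
def test_fisher_matches_oracle_on_random_tables(cells):
    a, b, c, d = cells
    table = [[a, b], [c, d]]
    assert fisher_exact_2x2(table) == pytest.approx(float(fisher_oracle(table)),
                                                    rel=1e-9, abs=1e-12)


def test_no_association_gives_p_one():
    geno = _geno_one_locus(["A/G"] * 3 + ["G/G"], ["A/G"] * 3 + ["G/G"])
    cands = snp_sex_association(geno, make_labels(4, 4))
    assert cands[0].p_value == 1.0


def _geno_one_locus(female_genotypes, male_genotypes):
    from radsexscreen import GenotypeMatrix, LocusInfo
    ids = [f"F{i+1}" for i in range(len(female_genotypes))] + \
          [f"M{i+1}" for i in range(len(male_genotypes))]
    geno = np.array([female_genotypes + male_genotypes], dtype=object)
    return GenotypeMatrix([LocusInfo("snp1", "sc1", 1, "G", "A")], ids, geno)


def test_monomorphic_and_single_sex_loci_skipped():
    geno = _geno_one_locus(["G/G", "G/G"], ["G/G", "G/G"])
    assert snp_sex_association(geno, make_labels(2, 2)) == []
    geno = _geno_one_locus(["A/G", "G/G"], ["./.", "./."])
    assert snp_sex_association(geno, make_labels(2, 2)) == []


def test_association_ranks_planted_loci_first():
    cfg = SimConfig(n_female=10, n_male=10, n_tags=0, n_sexlinked_tags_male=0,
                    n_sexlinked_tags_female=0, n_loci=100, n_sexlinked_loci=5,
                    q=0.0, r=0.0, missing_rate=0.0, seed=21)
    _, geno, labels, truth = simulate_population(cfg)
    cands = snp_sex_association(geno, labels)
    top = {c.locus_id for c in cands[:len(truth.sexlinked_loci)]}
    assert top == set(truth.sexlinked_loci)
    assert all(c.heterogamety_call == "ZW" for c in cands[:5])
    # BH q-values never fall below their p-values
    assert all(c.q_value >= c.p_value - 1e-12 for c in cands)
    assert all(0 < c.p_value <= 1 for c in cands)


def test_2x3_exact_p_agrees_with_collapse_when_classes_merge():
    # with only two occupied genotype classes the 2x3 test reduces to 2x2
    p23 = exact_2x3_p((0, 10, 0), (10, 0, 0))
    assert p23 == pytest.approx(2 / math.comb(20, 10), rel=1e-12)


# ---------------------------------------------------------------------------
# Top-k and heterogamety
# ---------------------------------------------------------------------------


def _cand(locus_id, p):
    return SnpCandidate(locus_id, {"female": (0, 1, 0), "male": (1, 0, 0)}, p)


def test_select_top_k_rules():
    cands = [_cand("b", 0.2), _cand("a", 0.2), _cand("c", 0.1)]
    top = select_top_k(cands, 2)
    assert [c.locus_id for c in top] == ["c", "a"]  # tie broken lexicographically
    assert len(select_top_k(cands, 10)) == 3  # saturates with a warning
    with pytest.raises(ValueError):
        select_top_k(cands, 0)


@pytest.mark.parametrize("counts_f,counts_m,expected", [
    ((0, 10, 0), (10, 0, 0), "ZW"),
    ((10, 0, 0), (0, 10, 0), "XY"),
    ((10, 0, 0), (10, 0, 0), "inconclusive"),
    ((0, 9, 1), (10, 0, 0), "inconclusive"),
    ((0, 0, 0), (10, 0, 0), "inconclusive"),
])
def test_classify_heterogamety(counts_f, counts_m, expected):
    cand = SnpCandidate("x", {"female": counts_f, "male": counts_m}, 0.5)
    assert classify_heterogamety(cand) == expected


def test_classify_heterogamety_min_fraction_relaxes_the_call():
    cand = SnpCandidate("x", {"female": (0, 9, 1), "male": (10, 0, 0)}, 0.5)
    assert classify_heterogamety(cand, min_fraction=0.9) == "ZW"
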