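"""Pair matrix, spacer classification, and the three permutation analyses."""

import itertools

import numpy as np
import pytest

from gutcrispr.stats import (
    build_pair_matrix,
    classify_spacers,
    cmh_permutation_test,
    cmh_statistic,
    count_shared_sequences,
    majority_foreign_count,
    position_permutation_test,
    read_pair_matrix_tsv,
    sharing_permutation_test,
    write_pair_matrix_tsv,
)
from gutcrispr.types import Cassette, PairMatrix, ProtospacerHit, Spacer


def _hit(cassette, serial, sp_ind, target, mm=0):
    sp = Spacer(cassette_id=cassette, serial=serial, interval=(0, 30), sequence="A" * 30)
    return ProtospacerHit(spacer=sp, spacer_individual=sp_ind,
                          target_contig_id=target, target_interval=(0, 30),
                          strand="+", mismatches=mm)


# --- pair matrix ---------------------------------------------------------

def test_pair_matrix_row_column_convention():
    hits = [_hit("k", 1, "A", "a.p1"), _hit("k", 2, "A", "a.p1"),
            _hit("k", 3, "A", "a.p2"), _hit("q", 1, "A", "b.p1")]
    m = build_pair_matrix(hits, ["A", "B"], {"a.p1": "A", "a.p2": "A", "b.p1": "B"})
    # rows = protospacer metagenomes, columns = spacer metagenomes
    assert m.counts[0, 0] == 3      # (proto A, spacer A)
    assert m.counts[1, 0] == 1      # (proto B, spacer A)
    assert m.total_pairs == 4


def test_pair_matrix_unknown_individual_excluded():
    hits = [_hit("k", 1, "A", "x")]
    m = build_pair_matrix(hits, ["A"], {})
    assert m.total_pairs == 0


def test_pair_matrix_tsv_roundtrip(tmp_path):
    m = PairMatrix(individuals=["A", "B", "C"],
                   counts=np.array([[3, 0, 1], [2, 5, 0], [0, 0, 0]]))
    p = tmp_path / "pairs.tsv"
    write_pair_matrix_tsv(m, p)
    back = read_pair_matrix_tsv(p)
    assert back.individuals == m.individuals
    assert (back.counts == m.counts).all()


def test_pair_matrix_to_pairs_inverse():
    m = PairMatrix(individuals=["A", "B"], counts=np.array([[2, 1], [0, 3]]))
    pairs = m.to_pairs()
    assert len(pairs) == 6
    assert pairs.count(("A", "A")) == 2     # (spacer A, proto A)
    assert pairs.count(("B", "A")) == 1     # (spacer B, proto A)
    assert pairs.count(("B", "B")) == 3


# --- classification ------------------------------------------------------

def test_classify_targeting_and_shared():
    spacers = [
        Spacer(cassette_id="k1", serial=1, interval=(0, 30), sequence="ACGTA" * 6),
        Spacer(cassette_id="k2", serial=1, interval=(0, 30), sequence="ACGTA" * 6),
        Spacer(cassette_id="k1", serial=2, interval=(40, 70), sequence="GGTAC" * 6),
    ]
    ind_of_cassette = {"k1": "A", "k2": "B"}
    ind_of_contig = {"phageA": "A", "phageB": "B"}
    hits = [_hit("k1", 1, "A", "phageA"),     # own individual: targeting
            _hit("k1", 2, "A", "phageB")]     # other individual only: not targeting
    targeting, shared = classify_spacers(spacers, hits, ind_of_cassette, ind_of_contig)
    assert targeting == {("k1", 1)}
    # identical sequence in individuals A and B: both occurrences shared
    assert shared == {("k1", 1), ("k2", 1)}


# --- position test -------------------------------------------------------

def _cassette(cid, n, leader="left", complete=True):
    spacers = [Spacer(cassette_id=cid, serial=i + 1,
                      interval=(100 + i * 60, 130 + i * 60), sequence="A" * 30)
               for i in range(n)]
    return Cassette(id=cid, contig_id="c", interval=(0, 100 + n * 60 + 40),
                    repeat_intervals=[(70, 100)], spacers=spacers,
                    repeat_consensus="A" * 30, leader_end=leader, complete=complete)


def test_position_test_matches_exact_enumeration():
    """One cassette of 5 spacers, single flagged spacer at the leader.

    Exact enumeration over the 5 equally likely positions gives a
    lower-tail p of 1/5; the Monte-Carlo estimate must sit within 3 SE.
    """
    cas = _cassette("x", 5)
    exact_p = 1 / 5
    n_perm = 10_000
    r = position_permutation_test([cas], {("x", 1)}, n_perm=n_perm, seed=3)
    se = np.sqrt(exact_p * (1 - exact_p) / n_perm)
    assert r.observed == 1.0
    assert abs(r.p_value - exact_p) < 3 * se


def test_position_test_exact_enumeration_multi_flag():
    """Two flagged spacers out of four: oracle enumerates all C(4,2) subsets."""
    cas = _cassette("y", 4)
    flagged = {("y", 1), ("y", 2)}   # observed sum 3, the minimum
    sums = [sum(c) for c in itertools.combinations(range(1, 5), 2)]
    exact_p = sum(s <= 3 for s in sums) / len(sums)
    r = position_permutation_test([cas], flagged, n_perm=20_000, seed=4)
    se = np.sqrt(exact_p * (1 - exact_p) / 20_000)
    assert abs(r.p_value - exact_p) < 3 * se


def test_position_test_all_flagged_is_invariant():
    cas = _cassette("x", 5)
    flagged = {("x", i) for i in range(1, 6)}
    lo = position_permutation_test([cas], flagged, n_perm=500, seed=0)
    hi = position_permutation_test([cas], flagged, n_perm=500, seed=0, tail="upper")
    assert lo.p_value == 1.0 and hi.p_value == 1.0


def test_position_test_eligibility_filters_and_error():
    bad = [_cassette("u", 4, leader="unknown"),
           _cassette("i", 4, complete=False)]
    with pytest.raises(ValueError, match="unoriented|incomplete"):
        position_permutation_test(bad, {("u", 1), ("i", 1)}, n_perm=10, seed=0)


def test_position_test_seed_reproducible_and_seed_robust():
    cassettes = [_cassette(f"c{k}", 6) for k in range(10)]
    flagged = {(f"c{k}", 1 + (k % 2)) for k in range(10)}
    a = position_permutation_test(cassettes, flagged, n_perm=4000, seed=1)
    b = position_permutation_test(cassettes, flagged, n_perm=4000, seed=1)
    c = position_permutation_test(cassettes, flagged, n_perm=4000, seed=2)
    assert a.p_value == b.p_value
    # two seeds agree within 4 Monte-Carlo standard errors
    p = (a.p_value + c.p_value) / 2
    se = np.sqrt(max(p * (1 - p), 1e-9) / 4000)
    assert abs(a.p_value - c.p_value) <= 4 * se + 1e-12


# --- sharing test --------------------------------------------------------

def test_sharing_disjoint_sets_constant_statistic():
    r = sharing_permutation_test(["A", "B"], [["s1", "s2"], ["s3", "s4"]],
                                 n_perm=300, seed=0)
    assert r.observed == 0.0 and r.p_value == 1.0
    assert r.null_sd == 0.0


def test_sharing_permutation_preserves_cassette_counts():
    rng = np.random.default_rng(8)
    inds = ["A"] * 3 + ["B"] * 2 + ["C"] * 4
    assignment = np.arange(len(inds))
    for _ in range(50):
        perm = rng.permutation(assignment)
        assert sorted(perm) == list(range(len(inds)))


def test_sharing_detects_excess_identity():
    # every cassette in A shares its spacer with one in B: observed = 3,
    # and no permutation can exceed the observed sharing
    cassettes = [["x1"], ["x2"], ["x3"], ["x1"], ["x2"], ["x3"]]
    inds = ["A", "A", "A", "B", "B", "B"]
    r = sharing_permutation_test(inds, cassettes, n_perm=2000, seed=5, tail="upper")
    assert r.observed == 3.0
    assert r.p_value <= 1.0
    assert r.null_mean <= 3.0


def test_sharing_single_individual_errors():
    with pytest.raises(ValueError):
        sharing_permutation_test(["A", "A"], [["s1"], ["s2"]], n_perm=10, seed=0)


def test_count_shared_sequences_oracle():
    # sequences 0 and 1; cassettes 0,1 -> ind 0; cassette 2 -> ind 1
    assignment = np.array([0, 0, 1])
    cassette_idx = np.array([0, 1, 2])
    seq_codes = np.array([0, 0, 1])
    assert count_shared_sequences(assignment, cassette_idx, seq_codes, 2) == 0
    assignment = np.array([0, 1, 1])
    assert count_shared_sequences(assignment, cassette_idx, seq_codes, 2) == 1


# --- CMH -----------------------------------------------------------------

def test_cmh_single_stratum_closed_form():
    """Hand evaluation: (a,b,c,d)=(10,0,0,10) in one stratum gives 19.0."""
    from gutcrispr.stats import _cmh_terms
    sp = np.array(["A"] * 10 + ["B"] * 10)
    pr = np.array(["A"] * 10 + ["B"] * 10)
    sum_a, sum_e, sum_v = _cmh_terms(sp, pr, np.array(["A"]))
    stat = (sum_a - sum_e) ** 2 / sum_v
    assert stat == pytest.approx(19.0)


def test_cmh_null_identity_is_zero():
    # independent margins: a_k equals its expectation in every stratum
    pairs = [(s, p) for s in "AB" for p in "AB"]   # uniform 2x2
    assert cmh_statistic(pairs) == pytest.approx(0.0)


def test_cmh_matches_reference_stratified_routine():
    """Frozen cross-check against R's mantelhaen.test on a random pair list."""
    rng = np.random.default_rng(42)
    inds = list("ABCDEF")
    pairs = [(inds[rng.integers(0, 6)], inds[rng.integers(0, 6)])
             for _ in range(200)]
    assert cmh_statistic(pairs) == pytest.approx(0.2445975254136847)
    assert cmh_statistic(pairs, continuity_correction=True) == pytest.approx(
        0.1527910802118483)


def test_cmh_invariant_to_relabeling():
    rng = np.random.default_rng(43)
    inds = list("ABCD")
    pairs = [(inds[rng.integers(0, 4)], inds[rng.integers(0, 4)])
             for _ in range(120)]
    relabel = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
    renamed = [(relabel[s], relabel[p]) for s, p in pairs]
    assert cmh_statistic(pairs) == pytest.approx(cmh_statistic(renamed))
    assert cmh_statistic(pairs) == pytest.approx(cmh_statistic(list(reversed(pairs))))


def test_cmh_degenerate_errors():
    with pytest.raises(ValueError):
        cmh_statistic([])
    with pytest.raises(ValueError):
        cmh_statistic([("A", "A")])    # single individual: all margins full


def test_cmh_permutation_diagonal_pairs_significant():
    """Perfect within-individual concordance is detected by the shuffle null."""
    pairs = [(i, i) for i in "ABC" for _ in range(8)]
    r = cmh_permutation_test(pairs, n_perm=2000, seed=9)
    assert r.p_value <= 0.01


def test_cmh_permutation_matches_full_recompute():
    """The margin-invariance shortcut equals recomputing CMH per draw."""
    rng = np.random.default_rng(44)
    inds = list("ABCD")
    pairs = [(inds[rng.integers(0, 4)], inds[rng.integers(0, 4)])
             for _ in range(60)]
    sp = [p[0] for p in pairs]
    pr = np.array([p[1] for p in pairs])
    r = cmh_permutation_test(pairs, n_perm=50, seed=10)
    rng2 = np.random.default_rng(10)
    null = []
    for _ in range(50):
        shuffled = rng2.permutation(pr)
        null.append(cmh_statistic(list(zip(sp, shuffled))))
    assert int(np.sum(np.array(null) >= r.observed)) == r.n_as_extreme


def test_cmh_permutation_calibration_under_exchangeable_labels():
    """With protospacer labels assigned independently of spacers, the
    permutation p-value is approximately uniform."""
    rng = np.random.default_rng(45)
    inds = list("ABCDE")
    ps = []
    for _ in range(60):
        pairs = [(inds[rng.integers(0, 5)], inds[rng.integers(0, 5)])
                 for _ in range(80)]
        r = cmh_permutation_test(pairs, n_perm=300, seed=int(rng.integers(2**31)))
        ps.append(r.p_value)
    from scipy import stats as sps
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# --- majority foreign ----------------------------------------------------

def test_majority_foreign_rules():
    m = PairMatrix(
        individuals=["A", "B", "C"],
        counts=np.array([
            [5, 0, 1],    # proto A
            [2, 0, 0],    # proto B
            [0, 0, 0],    # proto C
        ]),
    )
    # A: self 5 vs foreign 2 -> not counted; B: no pairs -> ineligible;
    # C: self 0 vs foreign 1 -> counted
    res = majority_foreign_count(m)
    assert res["count"] == 1
    assert res["n_with_pairs"] == 2
    assert res["fraction_of_with_pairs"] == pytest.approx(0.5)
    assert res["n_individuals"] == 3
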