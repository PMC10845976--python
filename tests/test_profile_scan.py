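import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famsurvey._alphabet import AMINO_ACIDS, NEG_SENTINEL, uniform_background
from famsurvey.profile_scan import (
    DegenerateAlignmentError,
    DomainHit,
    ScoringProfile,
    SeedAlignment,
    build_profile,
    determine_match_columns,
    filter_complete,
    profile_from_seed,
    read_profile,
    scan_protein,
    write_profile,
)
from famsurvey.profile_scan import _dp_best_hit, _emission_scores
from oracles import brute_force_local_alignment


def test_seed_alignment_validation():
    with pytest.raises(ValueError):
        SeedAlignment(("a",), ("ACD",))  # one row
    with pytest.raises(ValueError):
        SeedAlignment(("a", "a"), ("ACD", "ACD"))  # duplicate ids
    with pytest.raises(ValueError):
        SeedAlignment(("a", "b"), ("ACD", "AC"))  # ragged
    with pytest.raises(ValueError):
        SeedAlignment(("a", "b"), ("ACD", "AC!"))  # alphabet


def test_match_columns_threshold():
    aln = SeedAlignment(("a", "b", "c", "d"), ("ACD-", "AC-D", "A--D", "A---"))
    mask = determine_match_columns(aln, 0.5)
    # occupancies: 1.0, 0.5, 0.25, 0.5 -- the threshold is inclusive
    assert mask.tolist() == [True, True, False, True]


def test_match_columns_all_gap_error():
    aln = SeedAlignment(("a", "b"), ("--", "--"))
    with pytest.raises(DegenerateAlignmentError):
        determine_match_columns(aln)


def test_build_profile_log_odds_closed_form():
    # two rows, invariant 'A' column: e(A) = log2(((2 + 1*0.05)/(2+1))/0.05)
    aln = SeedAlignment(("a", "b"), ("A", "A"))
    prof = build_profile(aln, np.array([True]), pseudocount=1.0)
    expect_a = np.log2(((2 + 0.05) / 3) / 0.05)
    expect_other = np.log2(((0 + 0.05) / 3) / 0.05)
    assert prof.emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(expect_a)
    assert prof.emissions[0, AMINO_ACIDS.index("W")] == pytest.approx(expect_other)


def test_build_profile_zero_pseudocount_sentinel():
    aln = SeedAlignment(("a", "b"), ("A", "A"))
    prof = build_profile(aln, np.array([True]), pseudocount=0.0)
    assert prof.emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(np.log2(20))
    assert prof.emissions[0, AMINO_ACIDS.index("C")] == NEG_SENTINEL


def test_profile_emission_rows_are_proper_log_odds(profile):
    # expected score under background is negative for informative columns,
    # and 2^e weighted by background sums to 1 (probability normalization)
    bg = profile.background
    mass = (np.power(2.0, profile.emissions) * bg).sum(axis=1)
    assert np.allclose(mass, 1.0, atol=1e-9)


def test_domain_hit_consistency_enforced():
    with pytest.raises(ValueError):
        DomainHit("p", 1, 10, 5.0, 0.5, "AAAA")  # coverage says 0.5, string says 1.0
    h = DomainHit("p", 3, 6, 5.0, 0.75, "AA-A")
    assert h.domain_length == 4


def test_self_scan_scores_sum_of_column_maxima(profile):
    consensus = profile.consensus()
    hits = scan_protein(profile, consensus, "self")
    assert len(hits) >= 1
    assert hits[0].score == pytest.approx(profile.emissions.max(axis=1).sum(), abs=1e-4)
    assert hits[0].start == 1 and hits[0].end == len(consensus)
    assert hits[0].coverage == 1.0


def test_scan_locates_embedded_domain(profile, root_and_mask):
    root, _ = root_and_mask
    rng = np.random.default_rng(0)
    flank_l = "".join(rng.choice(list(AMINO_ACIDS), size=100))
    flank_r = "".join(rng.choice(list(AMINO_ACIDS), size=150))
    hits = scan_protein(profile, flank_l + root + flank_r, "emb")
    # best hit is the planted domain; chance flank alignments are partial
    # and fall to the completeness filter
    assert abs(hits[0].start - 101) <= 2
    assert abs(hits[0].end - (100 + len(root))) <= 2
    assert len(filter_complete(hits)) == 1


def test_scan_two_copies_found_separately(profile, root_and_mask):
    root, _ = root_and_mask
    rng = np.random.default_rng(1)
    spacer = "".join(rng.choice(list(AMINO_ACIDS), size=60))
    seq = root + spacer + root
    hits = scan_protein(profile, seq, "dup")
    assert len(hits) == 2
    spans = sorted((h.start, h.end) for h in hits)
    assert abs(spans[0][0] - 1) <= 2
    assert abs(spans[1][0] - (len(root) + 60 + 1)) <= 2
    # non-overlapping
    assert spans[0][1] < spans[1][0]


def test_scan_non_canonical_letters_tolerated(profile, root_and_mask):
    root, _ = root_and_mask
    noisy = "X" + root[1:-1] + "B"
    hits = scan_protein(profile, noisy, "noisy")
    assert len(hits) == 1
    assert hits[0].score > 100


def test_scan_empty_sequence_raises(profile):
    with pytest.raises(ValueError):
        scan_protein(profile, "")


def test_scan_profile_much_longer_than_protein_warns_empty(profile, caplog):
    hits = scan_protein(profile, "ACDEF", "short")
    assert hits == []


def test_filter_complete_thresholds():
    mk = lambda cov, score, L=10: DomainHit(
        "p", 1, 5, score, cov, "A" * int(cov * L) + "-" * (L - int(cov * L)))
    assert filter_complete([mk(1.0, 50.0)], 0.8, 15.0)
    assert not filter_complete([mk(0.5, 50.0)], 0.8, 15.0)
    assert not filter_complete([mk(1.0, 10.0)], 0.8, 15.0)
    with pytest.raises(ValueError):
        filter_complete([], coverage_min=1.5)


def test_profile_round_trip(tmp_path, profile):
    write_profile(profile, tmp_path / "p.tsv", tmp_path / "p.json")
    back = read_profile(tmp_path / "p.tsv", tmp_path / "p.json")
    assert np.allclose(back.emissions, profile.emissions, atol=1e-5)
    assert back.gap_open == profile.gap_open
    assert back.match_column_map == profile.match_column_map


def test_decoy_composition_shuffle_scores_below_threshold(profile, root_and_mask):
    root, _ = root_and_mask
    rng = np.random.default_rng(2)
    for _ in range(5):
        decoy = "".join(rng.permutation(list(root)))
        hits = scan_protein(profile, decoy, "decoy")
        assert filter_complete(hits) == []


# ---- DP against the exhaustive oracle ----

@given(st.integers(0, 10_000))
@settings(max_examples=60, deadline=None)
def test_dp_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(2, 6))
    n = int(rng.integers(2, 9))
    S = rng.normal(0.0, 2.0, size=(L, n))
    res = _dp_best_hit(S, gap_open=-3.0, gap_extend=-0.5)
    oracle = brute_force_local_alignment(S, gap_open=-3.0, gap_extend=-0.5)
    got = res[0] if res is not None else 0.0
    assert got == pytest.approx(oracle, abs=1e-9)


def test_dp_traceback_pairs_reproduce_score():
    rng = np.random.default_rng(42)
    for _ in range(20):
        L = int(rng.integers(3, 7))
        n = int(rng.integers(4, 12))
        S = rng.normal(0.5, 1.5, size=(L, n))
        res = _dp_best_hit(S, gap_open=-3.0, gap_extend=-0.5)
        if res is None:
            continue
        score, start, end, pairs = res
        poss = [p for _, p in pairs]
        assert min(poss) == start and max(poss) == end
        # recompute the score from the matched pairs and gap runs
        sp = sorted(pairs)
        assert all(c1 > c0 and p1 > p0 for (c0, p0), (c1, p1) in zip(sp, sp[1:]))
        total = sum(S[c - 1, p - 1] for c, p in sp)
        for (c0, p0), (c1, p1) in zip(sp, sp[1:]):
            dc, dp = c1 - c0 - 1, p1 - p0 - 1
            assert not (dc > 0 and dp > 0)  # no adjacent mixed gap runs
            if dc > 0:
                total += -3.0 + (dc - 1) * -0.5
            if dp > 0:
                total += -3.0 + (dp - 1) * -0.5
        assert total == pytest.approx(score, abs=1e-9)


def test_emission_scores_background_for_unknown(profile):
    S = _emission_scores(profile, "AX")
    expect = (profile.emissions * profile.background).sum(axis=1)
    assert np.allclose(S[:, 1], expect)
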