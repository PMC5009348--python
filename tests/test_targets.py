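"""Target prediction: seed types, alignment scoring, consensus, Alu flags."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alusel.targets import (
    AlignmentParams,
    MiRNA,
    TargetSite,
    align_miranda_like,
    classify_alu_sites,
    consensus_targets,
    duplex_energy,
    find_seed_sites,
    revcomp_rna,
)

MIR15A = MiRNA("miR-15a-3p", "CAGGCCAUAUUGUGCUGCCUCA")


def brute_force_seed_scan(utr: str, mirna: MiRNA):
    """Oracle: classify every window against the four canonical seed types."""
    utr = utr.upper().replace("T", "U")
    core = revcomp_rna(mirna.seed6)
    hits = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != core:
            continue
        has_m8 = i > 0 and utr[i - 1] == revcomp_rna(mirna.seed7)[0]
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            hits.append(("8mer", i - 1, i + 7))
        elif has_m8:
            hits.append(("7mer-m8", i - 1, i + 6))
        elif has_a1:
            hits.append(("7mer-A1", i, i + 7))
        else:
            hits.append(("6mer", i, i + 6))
    return hits


def test_8mer_worked_example():
    """The mature miRNA reconstructed from its published anti-miR finds its
    8mer site at 1-based positions 4-11."""
    sites = find_seed_sites("GGGAUGGCCUAGGG", MIR15A)
    assert len(sites) == 1
    s = sites[0]
    assert s.site_type == "8mer"
    assert (s.start, s.end) == (3, 11)
    assert "GGGAUGGCCUAGGG"[s.start:s.end] == "AUGGCCUA"


def test_7mer_m8_without_trailing_a():
    sites = find_seed_sites("AUGGCCU", MIR15A)
    assert [s.site_type for s in sites] == ["7mer-m8"]


def test_no_seed_no_sites():
    assert find_seed_sites("CCCCCCCCCCCCCC", MIR15A) == []


def test_seed_sites_reject_bad_alphabet():
    with pytest.raises(ValueError):
        find_seed_sites("AUGXCCUA", MIR15A)


def test_seed_sites_equal_bruteforce_on_random_utrs():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGU"))
    for _ in range(300):
        utr = "".join(rng.choice(bases, size=200))
        got = [(s.site_type, s.start, s.end) for s in find_seed_sites(utr, MIR15A)]
        assert got == brute_force_seed_scan(utr, MIR15A)


def test_alignment_perfect_complement_score():
    """Perfect 22-nt duplex: 7 seed positions x 5 x 4 + 15 x 5 = 215."""
    target = revcomp_rna(MIR15A.sequence)
    hits = align_miranda_like(target, MIR15A, AlignmentParams(score_threshold=100.0))
    assert len(hits) == 1
    assert hits[0].score == pytest.approx(215.0)
    assert (hits[0].start, hits[0].end) == (0, 22)


def test_alignment_no_complementarity_run_below_threshold():
    """A sequence with no extended complementarity to the miRNA cannot reach
    the genome-wide score threshold.  A homopolymer of A pairs only with the
    miRNA's scattered U positions, so every local alignment stays far below
    100 even with 4x seed scaling."""
    hits = align_miranda_like("A" * 50, MIR15A, AlignmentParams(score_threshold=100.0))
    assert hits == []


def test_alignment_hits_have_seed_complementarity():
    """Every >=100-score hit on random sequence owes its score to strong
    seed-region pairing (>= 5 Watson-Crick pairs among positions 2-8)."""
    rng = np.random.default_rng(7)
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    found = 0
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGU"), size=60))
        for hit in align_miranda_like(seq, MIR15A, AlignmentParams(score_threshold=100.0)):
            found += 1
            wc = sum(1 for t, m in hit.pairs if comp[m] == t)
            assert wc >= 5
    assert found > 0  # the scan does fire on some random sequences


def test_strict_seed_rejects_wobble_in_seed():
    """A G:U wobble at miRNA position 4 fails the strict-seed contract even
    though the total score clears the threshold."""
    target = list(revcomp_rna(MIR15A.sequence))
    # miRNA position 4 pairs with target index len-4; make it a G:U wobble
    pos4_target_index = len(target) - 4
    base = MIR15A.sequence[3]
    target[pos4_target_index] = "U" if base == "G" else "G"
    target = "".join(target)
    strict = AlignmentParams(score_threshold=100.0, strict_seed=True)
    loose = AlignmentParams(score_threshold=100.0, strict_seed=False)
    assert align_miranda_like(target, MIR15A, strict) == []
    assert len(align_miranda_like(target, MIR15A, loose)) == 1


def test_strict_subset_of_loose():
    rng = np.random.default_rng(3)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGU"), size=120))
        strict = align_miranda_like(
            seq, MIR15A, AlignmentParams(score_threshold=60.0, strict_seed=True))
        loose = align_miranda_like(
            seq, MIR15A, AlignmentParams(score_threshold=60.0, strict_seed=False))
        loose_spans = {(s.start, s.end) for s in loose}
        assert all((s.start, s.end) in loose_spans for s in strict)


def test_path_score_consistency():
    """Re-scoring the reported base pairs reproduces >= the pair part of the
    score (gaps only subtract)."""
    params = AlignmentParams(score_threshold=50.0)
    target = revcomp_rna(MIR15A.sequence)
    hit = align_miranda_like(target, MIR15A, params)[0]
    total = 0.0
    for k, (t, m) in enumerate(hit.pairs):
        pos = len(MIR15A.sequence) - k  # contiguous perfect duplex
    # perfect duplex: recompute directly
    m = MIR15A.sequence
    score = sum(
        5.0 * (4.0 if 2 <= pos <= 8 else 1.0) for pos in range(1, len(m) + 1)
    )
    assert hit.score == pytest.approx(score)


@pytest.mark.parametrize(
    "pairs,expected",
    [
        ([("G", "C")] * 10, -26.0),
        ([], 4.0),
        ([("A", "U")] * 5, -6.0),
    ],
)
def test_duplex_energy(pairs, expected):
    assert duplex_energy(pairs) == pytest.approx(expected)


def _site(utr, mir, start, end, predictor="seed_like"):
    return TargetSite(utr, mir, start, end, "6mer", predictor)


def test_consensus_overlap_kept():
    a = [_site("u1", "m1", 100, 107)]
    b = [_site("u1", "m1", 100, 108)]
    cons = consensus_targets(a, b)
    assert len(cons) == 1 and cons[0].predictor == "consensus"


def test_consensus_discordant_positions_excluded():
    """Same miRNA called by both predictors on one UTR but at disjoint
    positions: the pair is dropped entirely."""
    a = [_site("u1", "m1", 100, 107)]
    b = [_site("u1", "m1", 400, 407)]
    assert consensus_targets(a, b) == []


def test_consensus_requires_both_predictors():
    a = [_site("u1", "m1", 100, 107)]
    assert consensus_targets(a, []) == []


def test_consensus_monotone_under_removal():
    a = [_site("u1", "m1", 100, 107), _site("u1", "m1", 300, 307)]
    b = [_site("u1", "m1", 104, 111)]
    full = {(s.start, s.end) for s in consensus_targets(a, b)}
    reduced = {(s.start, s.end) for s in consensus_targets(a[:1], b)}
    assert reduced <= full


def test_classify_alu_sites():
    sites = [
        _site("g1", "m1", 10, 18),    # inside Alu
        _site("g1", "m1", 500, 508),  # outside
        _site("g2", "m1", 20, 28),    # inside
    ]
    alu = {"g1": [(0, 100)], "g2": [(0, 100)]}
    out = classify_alu_sites(sites, alu)
    assert [s.in_alu for s in out] == [True, False, True]
    assert [s.alu_exclusive for s in out] == [False, False, True]


def test_symmetry_revcomp_count():
    """Reverse-complementing both UTR and miRNA conserves alignment site count."""
    rng = np.random.default_rng(5)
    params = AlignmentParams(score_threshold=80.0)
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGU"), size=80))
        n1 = len(align_miranda_like(seq, MIR15A, params))
        mir_rc = MiRNA("rc", revcomp_rna(MIR15A.sequence))
        # reversing both strands mirrors the duplex; seed scaling moves with
        # the miRNA, so compare with scaling disabled
        p_flat = AlignmentParams(score_threshold=80.0, scale=1.0)
        n_f1 = len(align_miranda_like(seq, MIR15A, p_flat))
        n_f2 = len(align_miranda_like(revcomp_rna(seq), mir_rc, p_flat))
        assert n_f1 == n_f2
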