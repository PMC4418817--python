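"""Profile building, scanning semantics, cutoff calibration and hit calling."""

import numpy as np
import pytest

from flavoscan.riboswitch import (ProfileModel, build_profile, calibrate_cutoff,
                                  call_riboswitches, score_sequence)
from flavoscan.synthetic import sample_motif, training_alignment
from flavoscan.tu import TranscriptionalUnit

from .oracles import best_placement_oracle, pwm_score_oracle


def test_identical_ungapped_training_gives_log2_inverse_background():
    prof = build_profile(["ACGT", "ACGT"], pseudocount=0.0)
    cons = prof.consensus()
    assert cons == "ACGT"
    for p, base in enumerate(cons):
        assert prof.log_odds[p, "ACGT".index(base)] == pytest.approx(np.log2(1 / 0.25))
        # off-consensus entries are floored, not -inf
        assert np.isfinite(prof.log_odds[p]).all()


def test_uniform_column_scores_zero_bits():
    prof = build_profile(["A", "C", "G", "T"], pseudocount=0.0)
    assert prof.log_odds == pytest.approx(np.zeros((1, 4)))


def test_pseudocount_matrix_matches_hand_computation():
    seqs = ["ACGA", "ACGC", "AGGA", "ATGA"]
    prof = build_profile(seqs, pseudocount=1.0)
    # column 0: 4 A's -> (4+1)/(4+4) = 5/8
    assert prof.log_odds[0, 0] == pytest.approx(np.log2((5 / 8) / 0.25))
    # column 1: C,C,G,T -> C: (2+1)/8
    assert prof.log_odds[1, 1] == pytest.approx(np.log2((3 / 8) / 0.25))


def test_majority_gap_columns_dropped():
    prof = build_profile(["A-G", "A-G", "ACG", "A-G"])
    assert prof.length == 2  # middle column is 75% gaps


def test_empty_alignment_rejected():
    with pytest.raises(ValueError):
        build_profile([])


def test_consensus_scores_sum_of_maxima(profile):
    score, offset = score_sequence(profile, profile.consensus())
    assert score == pytest.approx(profile.max_score)
    assert offset == 0


def test_empty_sequence_scores_zero(profile):
    assert score_sequence(profile, "") == (0.0, 0)


def test_short_sequence_scored_at_truncated_placement(profile):
    seq = profile.consensus()[:50]
    score, offset = score_sequence(profile, seq)
    assert offset == 0
    assert score == pytest.approx(profile.log_odds.max(axis=1)[:50].sum())


def test_ambiguous_bases_contribute_zero_bits(profile):
    cons = profile.consensus()
    with_n = "N" * 10 + cons
    score, offset = score_sequence(profile, with_n)
    assert score == pytest.approx(profile.max_score)
    assert offset == 10


def test_best_placement_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    prof = build_profile(training_alignment(7, length=5, n=6))
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=12))
        want = best_placement_oracle(prof.log_odds, prof.background, seq)
        assert score_sequence(prof, seq) == pytest.approx(want)


def test_score_additivity_of_concatenated_halves(profile):
    cons = profile.consensus()
    half = profile.length // 2
    left = pwm_score_oracle(profile.log_odds[:half], profile.background, cons[:half], 0)
    right = pwm_score_oracle(profile.log_odds[half:], profile.background, cons[half:], 0)
    assert score_sequence(profile, cons)[0] == pytest.approx(left + right)


def test_profile_tsv_roundtrip(profile, tmp_path):
    path = tmp_path / "prof.tsv"
    profile.to_tsv(path)
    back = ProfileModel.from_tsv(path)
    assert back.name == profile.name
    np.testing.assert_allclose(back.log_odds, profile.log_odds, rtol=1e-9)


def test_calibrate_cutoff_is_minimum_of_anchor_scores():
    assert calibrate_cutoff([53.1, 51.34, 60.2]) == 51.34
    assert calibrate_cutoff([40.0]) == 40.0
    rng = np.random.default_rng(0)
    scores = rng.uniform(45, 90, size=100)
    assert calibrate_cutoff(scores) == min(scores)
    with pytest.raises(ValueError):
        calibrate_cutoff([])


def _planted_genome(profile, bits_by_tu, rng, spacer=30, gap=500):
    """One replicon with + strand monocistrons; a motif upstream of each keyed TU."""
    seq_parts, tus, cursor = [], [], 0
    for k in range(len(bits_by_tu) if isinstance(bits_by_tu, list) else 3):
        pad = gap
        bits = (bits_by_tu[k] if isinstance(bits_by_tu, list) else bits_by_tu.get(k))
        if bits is not None:
            motif = sample_motif(profile, bits, rng)
            left = pad - len(motif) - spacer
            seq_parts += ["".join(rng.choice(list("ACGT"), size=left)), motif,
                          "".join(rng.choice(list("ACGT"), size=spacer))]
        else:
            seq_parts.append("".join(rng.choice(list("ACGT"), size=pad)))
        cursor += pad
        gene = "ATG" + "".join(rng.choice(list("ACGT"), size=300)) + "TAA"
        seq_parts.append(gene)
        tus.append(TranscriptionalUnit(f"chr.TU{k}", [f"g{k}"], "chr", "+",
                                       (cursor, cursor + len(gene))))
        cursor += len(gene)
    return "".join(seq_parts), tus


def test_hits_called_per_tu_with_cutoff_suppression(profile):
    rng = np.random.default_rng(11)
    seq, tus = _planted_genome(profile, {0: 60.0, 1: 45.0, 2: None}, rng)
    hits = call_riboswitches({"g": {"chr": seq}}, {"g": tus}, profile, cutoff=51.34)
    assert [h.tu_id for h in hits] == ["chr.TU0"]
    assert hits[0].score >= 51.34
    # planted coordinates recovered: motif ends 30 bp before the gene start
    assert hits[0].end == tus[0].span[0] - 30
    assert all(h.score >= 51.34 for h in hits)


def test_two_tus_two_hits(profile):
    rng = np.random.default_rng(13)
    seq, tus = _planted_genome(profile, {0: 55.0, 1: 52.5, 2: None}, rng)
    hits = call_riboswitches({"g": {"chr": seq}}, {"g": tus}, profile)
    assert {h.tu_id for h in hits} == {"chr.TU0", "chr.TU1"}


def test_raising_cutoff_never_adds_hits(profile):
    rng = np.random.default_rng(17)
    seq, tus = _planted_genome(profile, {0: 70.0, 1: 55.0, 2: 52.0}, rng)
    genomes, tumap = {"g": {"chr": seq}}, {"g": tus}
    previous = None
    for cutoff in (40.0, 51.34, 56.0, 65.0, 80.0):
        n = len(call_riboswitches(genomes, tumap, profile, cutoff=cutoff))
        if previous is not None:
            assert n <= previous
        previous = n


def test_minus_strand_scan_equals_plus_strand_sense(profile):
    """A motif behind a '-' TU (reverse-complemented) scores as on the '+' sense."""
    rng = np.random.default_rng(19)
    motif = sample_motif(profile, 60.0, rng)
    rc = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    flank = "".join(rng.choice(list("ACGT"), size=200))
    gene = "".join(rng.choice(list("ACGT"), size=300))
    seq = gene + "".join(rng.choice(list("ACGT"), size=30)) + rc + flank
    tu = TranscriptionalUnit("chr.TU0", ["g0"], "chr", "-", (0, len(gene)))
    hits = call_riboswitches({"g": {"chr": seq}}, {"g": [tu]}, profile)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].score == pytest.approx(score_sequence(profile, motif)[0])
    # coordinates point at the reverse-complemented copy on the replicon
    assert seq[hits[0].start:hits[0].end] == rc
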