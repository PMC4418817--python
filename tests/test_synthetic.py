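"""Generator calibration: identity targets, motif bit levels, determinism, consistency."""

import numpy as np
import pytest

from flavoscan.io import read_fasta, read_gff3
from flavoscan.riboswitch import build_profile, score_sequence
from flavoscan.synthetic import (CohortConfig, PackingError, TruthTable, generate_cohort,
                                 mutate_to_identity, random_cohort_config, sample_motif,
                                 synthetic_prototypes, training_alignment)

from .oracles import nw_global_identity


def test_mutate_target_one_returns_sequence_unchanged():
    assert mutate_to_identity("MKTAYEHW", 1.0, 0) == "MKTAYEHW"


def test_mutate_target_zero_single_residue_forced_change():
    assert mutate_to_identity("W", 0.0, 0) != "W"


def test_mutate_realizes_global_identity_within_band(rng):
    proto = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
    mut = mutate_to_identity(proto, 0.38, 7)
    ident = nw_global_identity(mut, proto)
    assert 0.35 <= ident <= 0.41


def test_identity_calibration_over_many_draws(rng):
    """Mean |realized - target| <= 0.02 (measured by the global-alignment oracle)."""
    proto = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
    errs = []
    for seed in range(50):
        target = 0.3 + 0.5 * (seed / 49)
        mut = mutate_to_identity(proto, target, seed)
        errs.append(abs(nw_global_identity(mut, proto) - target))
    assert np.mean(errs) <= 0.02


def test_sample_motif_consensus_is_maximum(profile):
    motif = sample_motif(profile, profile.max_score, 0)
    assert motif == profile.consensus()


def test_sample_motif_hits_target_levels(profile):
    for target in (51.34, 56.34, 30.0, 0.0):
        motif = sample_motif(profile, target, 3)
        score, _ = score_sequence(profile, motif)
        assert abs(score - target) <= 2.0


def test_sample_motif_rejects_unattainable_target(profile):
    with pytest.raises(ValueError):
        sample_motif(profile, profile.max_score + 5, 0)


def test_random_background_scores_far_below_cutoff(profile):
    """Random intergenic DNA of motif length stays >=10 bits under 51.34 almost surely."""
    rng = np.random.default_rng(42)
    below = sum(
        score_sequence(profile, "".join(rng.choice(list("ACGT"), size=profile.length)))[0]
        < 51.34 - 10.0
        for _ in range(1000))
    assert below >= 990


def test_empty_cohort(tmp_path):
    cohort, truth = generate_cohort(CohortConfig(n_genomes=0), tmp_path / "c0")
    assert cohort.genomes == {}
    assert truth.planted_riboswitches == [] and truth.planted_orthologs == []


def test_identity_target_one_plants_exact_prototype(tmp_path):
    cfg = CohortConfig(
        n_genomes=1, families_present={"g000": {"RibZ"}},
        family_identity_targets={("g000", "RibZ"): 1.0},
        rbp_truth={"g000": False}, taxonomy={"g000": "Firmicutes"}, seed=5)
    cohort, truth = generate_cohort(cfg, tmp_path / "c1")
    planted = truth.planted_orthologs[0]
    assert planted.realized_identity == 1.0
    assert cohort.proteomes["g000"][planted.gene_id] == synthetic_prototypes()["RibZ"]


def test_planted_identity_measured_by_oracle(tmp_path):
    cfg = CohortConfig(
        n_genomes=1, families_present={"g000": {"RibU"}},
        family_identity_targets={("g000", "RibU"): 0.5},
        rbp_truth={"g000": True}, taxonomy={"g000": "Firmicutes"}, seed=1)
    cohort, truth = generate_cohort(cfg, tmp_path / "c2")
    planted = truth.planted_orthologs[0]
    seq = cohort.proteomes["g000"][planted.gene_id]
    assert 0.47 <= nw_global_identity(seq, synthetic_prototypes()["RibU"]) <= 0.53


def test_generation_is_byte_identical_under_fixed_seed(tmp_path):
    cfg = random_cohort_config(3, seed=9)
    generate_cohort(cfg, tmp_path / "a")
    generate_cohort(cfg, tmp_path / "b")
    for p in sorted((tmp_path / "a").rglob("*")):
        if p.is_file():
            q = tmp_path / "b" / p.relative_to(tmp_path / "a")
            assert q.read_bytes() == p.read_bytes(), p.name


def test_annotation_consistency(tmp_path):
    """Every GFF3 feature maps to one protein record and lies within its replicon."""
    cfg = random_cohort_config(3, seed=21)
    cohort, _ = generate_cohort(cfg, tmp_path / "c")
    for genome in cohort.genomes:
        genes = read_gff3(tmp_path / "c" / f"{genome}.gff3")
        proteins = read_fasta(tmp_path / "c" / f"{genome}.faa")
        seqs = read_fasta(tmp_path / "c" / f"{genome}.fna")
        flat = [g for rep in genes.values() for g in rep]
        assert sorted(g.id for g in flat) == sorted(proteins)
        for g in flat:
            assert 0 <= g.start < g.end <= len(seqs[g.replicon])


def test_planted_motif_scores_within_two_bits_of_target(tmp_path):
    cfg = random_cohort_config(4, seed=33)
    cohort, truth = generate_cohort(cfg, tmp_path / "c")
    assert truth.planted_riboswitches
    for p in truth.planted_riboswitches:
        seq = cohort.genomes[p.genome][p.replicon][p.start:p.end]
        if p.strand == "-":
            seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        score, _ = score_sequence(cohort.profile, seq)
        assert abs(score - p.target_bits) <= 2.0


def test_infeasible_packing_names_genome(tmp_path):
    cfg = random_cohort_config(1, seed=2, genome_length=1000)
    with pytest.raises(PackingError, match="g000"):
        generate_cohort(cfg, tmp_path / "c")


def test_truth_table_roundtrip(tmp_path):
    cfg = random_cohort_config(3, seed=13)
    _, truth = generate_cohort(cfg, tmp_path / "c")
    back = TruthTable.from_dir(tmp_path / "c" / "truth")
    assert back.rbp_status == truth.rbp_status
    assert [(p.genome, p.tu_id) for p in back.planted_riboswitches] == \
        [(p.genome, p.tu_id) for p in truth.planted_riboswitches]
    assert len(back.planted_orthologs) == len(truth.planted_orthologs)


def test_identity_target_out_of_range_rejected():
    cfg = CohortConfig(
        n_genomes=1, families_present={"g000": {"RibZ"}},
        family_identity_targets={("g000", "RibZ"): 1.5},
        rbp_truth={"g000": False}, taxonomy={"g000": "Firmicutes"})
    with pytest.raises(ValueError, match="identity target"):
        cfg.validate()
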