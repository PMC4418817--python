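"""Synthetic genome cohorts with planted ground truth.

Everything the downstream stages assume is emulated here with explicit,
seeded statistical structure: genomes laid out as operon blocks at
controlled intergenic distances, riboswitch motif instances sampled from the
profile at controlled bit-score levels, transporter genes mutated to target
identity/coverage against each family prototype, biosynthesis marker genes
present or absent per a truth table, and a star-evolved marker alignment for
the display phylogeny.

The generator is deterministic: one random stream per genome, derived from
the master seed by genome index, so identical configurations produce
byte-identical output files and truth tables.

All sequences here (prototypes included) are synthetic stand-ins; no real
genomic or protein accessions are embedded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .orthology import FAMILIES, FamilyPrototype, make_prototypes
from .riboswitch import ProfileModel, build_profile, score_sequence
from .tu import Gene, DEFAULT_WINDOW

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# fixed single-codon back-translation (one codon per residue + TAA stop)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_PROTOTYPE_SEED = 715  # fixed so prototypes are stable across cohorts
_PHYLA = ("Actinobacteria", "Chloroflexi", "Proteobacteria", "Firmicutes",
          "Fusobacteria", "Tenericutes", "Dictyoglomi", "Spirochaetes", "Thermobaculum")
RBP_MARKER_FAMILIES = ("COG0054", "COG0307")

DEFAULT_MOTIF_LENGTH = 140
DEFAULT_SPACER = 30


class PackingError(ValueError):
    """Raised when a genome's genes cannot fit at the requested distances."""


@dataclass
class CohortConfig:
    """Generative conditions for one synthetic cohort."""

    n_genomes: int
    families_present: dict[str, set] = field(default_factory=dict)
    family_identity_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    rbp_truth: dict[str, bool] = field(default_factory=dict)
    riboswitch_truth: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    taxonomy: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    genome_length: int | None = None  # None: smallest length that fits the layout
    genes_per_genome: int = 12
    same_operon_gap_mean: float = 20.0
    between_operon_gap_mean: float = 500.0
    between_operon_gap_min: int = 400
    gc: float | None = None  # None: uniform over A,C,G,T
    motif_length: int = DEFAULT_MOTIF_LENGTH
    upstream_spacer: int = DEFAULT_SPACER
    window: int = DEFAULT_WINDOW

    def genome_names(self) -> list[str]:
        names = set(self.taxonomy) | set(self.families_present) | set(self.rbp_truth)
        if not names:
            names = {f"g{i:03d}" for i in range(self.n_genomes)}
        out = sorted(names)
        if len(out) != self.n_genomes:
            raise ValueError(f"config names {len(out)} genomes but n_genomes={self.n_genomes}")
        return out

    def validate(self) -> None:
        names = set(self.genome_names())
        for (g, fam), t in self.family_identity_targets.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"identity target for ({g}, {fam}) outside [0, 1]: {t}")
        for g, fams in self.families_present.items():
            if g not in names:
                raise ValueError(f"families_present names unknown genome {g!r}")
            for fam in fams:
                if (g, fam) not in self.family_identity_targets:
                    raise ValueError(f"no identity target for planted family ({g}, {fam})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        if "families_present" in raw:
            raw["families_present"] = {g: set(v) for g, v in raw["families_present"].items()}
        if "family_identity_targets" in raw:
            tgt = {}
            for key, v in raw["family_identity_targets"].items():
                if isinstance(key, str):
                    g, fam = key.split("/")
                else:
                    g, fam = key
                tgt[(g, fam)] = float(v)
            raw["family_identity_targets"] = tgt
        if "riboswitch_truth" in raw:
            raw["riboswitch_truth"] = {
                g: [(int(i), float(b)) for i, b in v]
                for g, v in raw["riboswitch_truth"].items()
            }
        return cls(**raw)


@dataclass
class PlantedRiboswitch:
    genome: str
    replicon: str
    start: int
    end: int
    strand: str
    tu_id: str
    target_bits: float
    realized_bits: float


@dataclass
class PlantedOrtholog:
    genome: str
    gene_id: str
    family: str
    target_identity: float
    realized_identity: float
    realized_coverage: float


@dataclass
class TruthTable:
    planted_riboswitches: list[PlantedRiboswitch] = field(default_factory=list)
    planted_orthologs: list[PlantedOrtholog] = field(default_factory=list)
    rbp_status: dict[str, bool] = field(default_factory=dict)

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "riboswitches.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["genome", "replicon", "start", "end", "strand", "tu_id",
                        "target_bits", "realized_bits"])
            for p in self.planted_riboswitches:
                w.writerow([p.genome, p.replicon, p.start, p.end, p.strand, p.tu_id,
                            f"{p.target_bits:.4f}", f"{p.realized_bits:.4f}"])
        with open(out / "orthologs.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["genome", "gene_id", "family", "target_identity",
                        "realized_identity", "realized_coverage"])
            for p in self.planted_orthologs:
                w.writerow([p.genome, p.gene_id, p.family, f"{p.target_identity:.4f}",
                            f"{p.realized_identity:.6f}", f"{p.realized_coverage:.6f}"])
        with open(out / "rbp.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["genome", "rbp"])
            for g in sorted(self.rbp_status):
                w.writerow([g, int(self.rbp_status[g])])

    @classmethod
    def from_dir(cls, path: str | Path) -> "TruthTable":
        path = Path(path)
        tt = cls()
        with open(path / "riboswitches.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                tt.planted_riboswitches.append(PlantedRiboswitch(
                    row["genome"], row["replicon"], int(row["start"]), int(row["end"]),
                    row["strand"], row["tu_id"], float(row["target_bits"]),
                    float(row["realized_bits"])))
        with open(path / "orthologs.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                tt.planted_orthologs.append(PlantedOrtholog(
                    row["genome"], row["gene_id"], row["family"],
                    float(row["target_identity"]), float(row["realized_identity"]),
                    float(row["realized_coverage"])))
        with open(path / "rbp.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                tt.rbp_status[row["genome"]] = bool(int(row["rbp"]))
        return tt


@dataclass
class Cohort:
    """In-memory view of a generated cohort (files are also written to disk)."""

    config: CohortConfig
    genomes: dict[str, dict[str, str]]          # genome -> replicon -> sequence
    genes: dict[str, list[Gene]]                # genome -> genes (genomic order)
    proteomes: dict[str, dict[str, str]]        # genome -> gene id -> protein
    profile: ProfileModel
    prototypes: list[FamilyPrototype]
    taxonomy: dict[str, str]
    marker_alignment: list[tuple[str, str]]
    truth: TruthTable
    out_dir: Path | None = None


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _random_dna(rng: np.random.Generator, length: int, gc: float | None = None) -> str:
    if length <= 0:
        return ""
    if gc is None:
        p = None
    else:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def encode_protein(protein: str) -> str:
    """Fixed-codon back-translation plus a TAA stop."""
    return "".join(_CODON[aa] for aa in protein) + "TAA"


def synthetic_prototypes(seed: int = _PROTOTYPE_SEED) -> dict[str, str]:
    """Deterministic synthetic stand-in prototype per transporter family."""
    rng = np.random.default_rng(seed)
    out = {}
    for fam in FAMILIES:
        length = int(rng.integers(110, 190))
        out[fam] = _random_protein(rng, length)
    return out


def synthetic_marker_prototypes(seed: int = _PROTOTYPE_SEED + 1) -> dict[str, str]:
    """Synthetic stand-ins for the two biosynthesis marker families."""
    rng = np.random.default_rng(seed)
    return {fam: _random_protein(rng, int(rng.integers(140, 180)))
            for fam in RBP_MARKER_FAMILIES}


def mutate_to_identity(prototype: str, target: float, seed_or_rng,
                       indel_frac: float = 0.0) -> str:
    """Mutate a protein to a target global identity (+-0.03).

    Substitutions are sampled uniformly over the 19 alternative residues at
    ``round((1 - target) * L)`` distinct positions, which realizes the target
    exactly up to rounding. ``indel_frac`` (capped at 5% of length) optionally
    adds short indels at the expense of exactness.
    """
    if not prototype:
        raise ValueError("prototype must be non-empty")
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"identity target outside [0, 1]: {target}")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    L = len(prototype)
    n_mut = int(round((1.0 - target) * L))
    seq = list(prototype)
    for pos in rng.choice(L, size=n_mut, replace=False):
        alternatives = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    if indel_frac > 0:
        n_indel = min(int(round(indel_frac * L)), int(round(0.05 * L)))
        for _ in range(n_indel):
            pos = int(rng.integers(len(seq)))
            if rng.random() < 0.5 and len(seq) > 1:
                del seq[pos]
            else:
                seq.insert(pos, AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))])
    return "".join(seq)


def training_alignment(seed: int, length: int = DEFAULT_MOTIF_LENGTH,
                       n: int = 20) -> list[tuple[str, str]]:
    """Seeded riboswitch training alignment with heterogeneous column conservation.

    Column mutation rates are drawn from U(0.05, 0.4) so the resulting profile
    has positions of varying strength; that graded score landscape is what
    lets :func:`sample_motif` dial a sequence to an arbitrary bit level.
    """
    rng = np.random.default_rng(seed)
    consensus = rng.choice(list("ACGT"), size=length)
    rates = rng.uniform(0.05, 0.4, size=length)
    rows = []
    for i in range(n):
        row = consensus.copy()
        mutate = rng.random(length) < rates
        for p in np.where(mutate)[0]:
            choices = [b for b in "ACGT" if b != consensus[p]]
            row[p] = choices[int(rng.integers(3))]
        rows.append((f"train{i:02d}", "".join(row)))
    return rows


def sample_motif(profile: ProfileModel, target_bits: float, seed_or_rng,
                 tolerance: float = 0.5, max_passes: int = 20) -> str:
    """A sequence scoring within +-2 bits of ``target_bits`` under the profile.

    Starts from the profile consensus (the maximum-scoring string for a
    position-wise profile) and greedily swaps bases at randomly ordered
    positions toward the target. Raises when the target exceeds the profile's
    maximum attainable score.
    """
    if target_bits > profile.max_score + 1e-9:
        raise ValueError(f"target {target_bits} bits exceeds profile maximum "
                         f"{profile.max_score:.2f}")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    lo = profile.log_odds
    state = lo.argmax(axis=1).astype(int)
    score = float(lo.max(axis=1).sum())
    L = profile.length
    for _ in range(max_passes):
        if abs(score - target_bits) <= tolerance:
            break
        for p in rng.permutation(L):
            cur = lo[p, state[p]]
            deltas = lo[p] - cur
            gains = np.abs(score + deltas - target_bits)
            b = int(np.argmin(gains))
            if gains[b] < abs(score - target_bits) - 1e-12:
                score += float(deltas[b])
                state[p] = b
            if abs(score - target_bits) <= tolerance:
                break
    return "".join("ACGT"[b] for b in state)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class _Operon:
    genes: list[tuple[str, str, str | None]]  # (gene_id_suffixless protein, family label)
    strand: str
    riboswitch_bits: float | None = None


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> tuple[Cohort, TruthTable]:
    """Generate and write a full cohort; returns the in-memory view and truth.

    Per genome: planted transporter monocistrons first (sorted by family),
    then the two-gene biosynthesis marker operon when the genome is RBP+,
    then filler operons, each separated by between-operon gaps and with
    riboswitch motifs inserted in the upstream spacer of the designated
    transcriptional units.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = config.genome_names()

    master = np.random.SeedSequence(config.seed)
    train_seed, marker_seed = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(2)]
    genome_rngs = _child_rngs(config.seed + 1, max(config.n_genomes, 1))

    train = training_alignment(train_seed, length=config.motif_length)
    profile = build_profile(train, pseudocount=1.0)
    proto_seqs = synthetic_prototypes()
    prototypes = make_prototypes(proto_seqs)
    marker_protos = synthetic_marker_prototypes()

    truth = TruthTable()
    genomes: dict[str, dict[str, str]] = {}
    all_genes: dict[str, list[Gene]] = {}
    proteomes: dict[str, dict[str, str]] = {}
    taxonomy = {g: config.taxonomy.get(g, "unknown") for g in names}

    # star-evolved marker alignment for the display tree
    marker_rng = np.random.default_rng(marker_seed)
    marker_root = _random_protein(marker_rng, 120)
    marker_rows: list[tuple[str, str]] = []

    for gi, genome in enumerate(names):
        rng = genome_rngs[gi]
        replicon = f"{genome}_chr"
        fams = sorted(config.families_present.get(genome, set()))
        rbp = bool(config.rbp_truth.get(genome, False))
        ribo_map = dict(config.riboswitch_truth.get(genome, []))

        # marker alignment row (star phylogeny, genome-specific rate)
        rate = rng.uniform(0.05, 0.3)
        row = "".join(
            (a if rng.random() >= rate
             else AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))])
            for a in marker_root)
        marker_rows.append((genome, row))

        # build operons: transporters, marker operon, fillers
        operons: list[_Operon] = []
        planted: list[tuple[int, str, str, float]] = []  # (operon idx, family, protein, target)
        for fam in fams:
            target = config.family_identity_targets[(genome, fam)]
            prot = mutate_to_identity(proto_seqs[fam], target, rng)
            operons.append(_Operon(genes=[(prot, fam)], strand="+-"[int(rng.integers(2))]))
            planted.append((len(operons) - 1, fam, prot, target))
        if rbp:
            mg = [(mutate_to_identity(marker_protos[m], 0.9, rng), m)
                  for m in RBP_MARKER_FAMILIES]
            operons.append(_Operon(genes=mg, strand="+-"[int(rng.integers(2))]))
        n_planted_genes = sum(len(op.genes) for op in operons)
        n_filler = max(0, config.genes_per_genome - n_planted_genes)
        while n_filler > 0:
            size = min(int(rng.integers(1, 4)), n_filler)
            gsz = [(_random_protein(rng, int(rng.integers(80, 140))), None)
                   for _ in range(size)]
            operons.append(_Operon(genes=gsz, strand="+-"[int(rng.integers(2))]))
            n_filler -= size
        for idx, bits in ribo_map.items():
            if idx >= len(operons):
                raise ValueError(f"genome {genome}: riboswitch TU index {idx} out of range")
            operons[idx].riboswitch_bits = bits

        # lay out the replicon
        motif_room = config.motif_length + config.upstream_spacer + 10
        parts: list[str] = []
        cursor = 0
        genes: list[Gene] = []
        proteome: dict[str, str] = {}
        gene_counter = 0
        lead = max(config.window, motif_room)
        pending_minus_motif: str | None = None  # RC motif to place after a '-' operon

        def emit_gap(length: int, motif: str | None = None):
            """Append an intergenic gap; an embedded motif ends ``spacer`` bp
            before the gap's right edge (i.e. just upstream of a '+' operon).
            Returns the motif's (start, end) on the replicon, or None."""
            nonlocal cursor
            if motif is None:
                parts.append(_random_dna(rng, length, config.gc))
                cursor += length
                return None
            mlen = len(motif)
            if length < mlen + config.upstream_spacer:
                length = mlen + config.upstream_spacer + 10
            left = length - mlen - config.upstream_spacer
            parts.append(_random_dna(rng, left, config.gc))
            mstart = cursor + left
            parts.append(motif)
            parts.append(_random_dna(rng, config.upstream_spacer, config.gc))
            cursor += length
            return mstart, mstart + mlen

        for oi, op in enumerate(operons):
            gap = lead if oi == 0 else max(
                config.between_operon_gap_min,
                int(round(rng.normal(config.between_operon_gap_mean,
                                     config.between_operon_gap_mean * 0.15))))
            realized = target = None
            if op.riboswitch_bits is not None:
                motif = sample_motif(profile, op.riboswitch_bits, rng)
                realized, _ = score_sequence(profile, motif)
                target = op.riboswitch_bits
                if op.strand == "-":
                    pending_minus_motif = motif

            if op.strand == "+" and op.riboswitch_bits is not None:
                span = emit_gap(gap, motif)
                truth.planted_riboswitches.append(PlantedRiboswitch(
                    genome, replicon, span[0], span[1], "+",
                    f"{replicon}.TU{oi}", target, realized))
            else:
                emit_gap(gap)

            # genes of the operon, left-to-right on the replicon
            gene_seqs = op.genes if op.strand == "+" else op.genes[::-1]
            op_gene_ids = []
            for k, (prot, fam) in enumerate(gene_seqs):
                if k > 0:
                    intra = max(0, int(round(rng.normal(config.same_operon_gap_mean,
                                                        config.same_operon_gap_mean * 0.3))))
                    parts.append(_random_dna(rng, intra, config.gc))
                    cursor += intra
                dna = encode_protein(prot)
                if op.strand == "-":
                    dna = _revcomp(dna)
                gid = f"{genome}_g{gene_counter:04d}"
                gene_counter += 1
                genes.append(Gene(id=gid, replicon=replicon, start=cursor,
                                  end=cursor + len(dna), strand=op.strand,
                                  product_family=fam))
                proteome[gid] = prot
                parts.append(dna)
                cursor += len(dna)
                op_gene_ids.append((gid, fam))

            # planted-ortholog truth rows for this operon
            for pi, fam, prot, tgt in planted:
                if pi == oi:
                    gid = next(g for g, f in op_gene_ids if f == fam)
                    realized_id = sum(a == b for a, b in zip(prot, proto_seqs[fam])) \
                        / len(proto_seqs[fam])
                    truth.planted_orthologs.append(PlantedOrtholog(
                        genome, gid, fam, tgt, realized_id, 1.0))

            # a '-' strand operon's riboswitch sits in the gap to its right
            if op.strand == "-" and op.riboswitch_bits is not None:
                motif_rc = _revcomp(pending_minus_motif)
                mstart = cursor + config.upstream_spacer
                parts.append(_random_dna(rng, config.upstream_spacer, config.gc))
                parts.append(motif_rc)
                cursor = mstart + len(motif_rc)
                truth.planted_riboswitches.append(PlantedRiboswitch(
                    genome, replicon, mstart, cursor, "-",
                    f"{replicon}.TU{oi}", target, realized))
                pending_minus_motif = None

        tail = max(config.window, motif_room)
        parts.append(_random_dna(rng, tail, config.gc))
        cursor += tail
        seq = "".join(parts)
        if config.genome_length is not None:
            if len(seq) > config.genome_length:
                raise PackingError(
                    f"genome {genome}: layout needs {len(seq)} bp but genome_length is "
                    f"{config.genome_length}")
            seq += _random_dna(rng, config.genome_length - len(seq), config.gc)

        genomes[genome] = {replicon: seq}
        all_genes[genome] = genes
        proteomes[genome] = proteome
        truth.rbp_status[genome] = rbp

        fio.write_fasta(out / f"{genome}.fna", [(replicon, seq)])
        fio.write_gff3(out / f"{genome}.gff3", genes, {replicon: len(seq)})
        fio.write_fasta(out / f"{genome}.faa",
                        [(gid, proteome[gid]) for gid in sorted(proteome)])

    # cohort-level files
    fio.write_fasta(out / "prototypes.faa",
                    [(fam, proto_seqs[fam], "synthetic stand-in prototype")
                     for fam in sorted(proto_seqs)])
    fio.write_fasta(out / "riboswitch_training.afa", train)
    profile.to_tsv(out / "profile.tsv")
    fio.write_fasta(out / "markers.afa", marker_rows)
    with open(out / "taxonomy.tsv", "w") as fh:
        fh.write("genome\tphylum\n")
        for g in names:
            fh.write(f"{g}\t{taxonomy[g]}\n")
    truth.to_dir(out / "truth")

    cohort = Cohort(config=config, genomes=genomes, genes=all_genes, proteomes=proteomes,
                    profile=profile, prototypes=prototypes, taxonomy=taxonomy,
                    marker_alignment=marker_rows, truth=truth, out_dir=out)
    return cohort, truth


def random_cohort_config(
    n_genomes: int,
    seed: int,
    genes_per_genome: int = 12,
    riboswitch_bits: tuple[float, float] = (56.34, 76.34),
    identity_present: float = 0.55,
    identity_decoy: float = 0.20,
    p_transporter: float = 0.7,
    p_second_family: float = 0.25,
    p_decoy: float = 0.3,
    p_rbp: float = 0.7,
    p_riboswitch_on_rbp: float = 0.8,
    **kwargs,
) -> CohortConfig:
    """Sample a cohort configuration with planted families, decoys and riboswitches.

    Transporter genes are planted well above the identity floor
    (``identity_present``) or well below it (``identity_decoy`` decoys);
    riboswitch motifs go upstream of every true transporter unit and, with
    probability ``p_riboswitch_on_rbp``, upstream of the biosynthesis marker
    operon (those are the calibration anchors).
    """
    rng = np.random.default_rng(seed)
    names = [f"g{i:03d}" for i in range(n_genomes)]
    fams_present: dict[str, set] = {}
    targets: dict[tuple[str, str], float] = {}
    rbp_truth: dict[str, bool] = {}
    ribo_truth: dict[str, list[tuple[int, float]]] = {}
    taxonomy: dict[str, str] = {}
    lo, hi = riboswitch_bits
    for g in names:
        taxonomy[g] = _PHYLA[int(rng.integers(len(_PHYLA)))]
        fams = set()
        if rng.random() < p_transporter:
            fams.add(FAMILIES[int(rng.integers(len(FAMILIES)))])
            if rng.random() < p_second_family:
                fams.add(FAMILIES[int(rng.integers(len(FAMILIES)))])
        decoys = set()
        if rng.random() < p_decoy:
            cand = [f for f in FAMILIES if f not in fams]
            decoys.add(cand[int(rng.integers(len(cand)))])
        ordered = sorted(fams | decoys)
        for fam in ordered:
            targets[(g, fam)] = identity_decoy if fam in decoys else identity_present
        fams_present[g] = fams | decoys
        rbp = bool(rng.random() < p_rbp)
        rbp_truth[g] = rbp
        ribo: list[tuple[int, float]] = []
        for idx, fam in enumerate(ordered):
            if fam in fams:  # riboswitch only on true transporters
                ribo.append((idx, float(rng.uniform(lo, hi))))
        if rbp and rng.random() < p_riboswitch_on_rbp:
            ribo.append((len(ordered), float(rng.uniform(lo, hi))))
        ribo_truth[g] = ribo
    return CohortConfig(
        n_genomes=n_genomes, families_present=fams_present,
        family_identity_targets=targets, rbp_truth=rbp_truth,
        riboswitch_truth=ribo_truth, taxonomy=taxonomy,
        seed=int(rng.integers(2**31)), genes_per_genome=genes_per_genome, **kwargs)
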