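"""Genome-level co-occurrence of riboflavin biosynthesis and transport.

A genome is a riboflavin producer (RBP+) only when BOTH marker families are
present: a COG0054-like and a COG0307-like gene, the last two steps of the
biosynthetic pathway. A single-marker genome is reported RBP- with a
``partial_rbp`` flag. Combining RBP status with the transporter-family call
set yields four mutually exclusive categories whose tallies satisfy
``transporter_total = both + transporter_only``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .orthology import OrthologCall

log = logging.getLogger(__name__)

RBP_MARKERS = ("COG0054", "COG0307")

CAT_BOTH = "RBP+transporter"
CAT_TRANSPORTER_ONLY = "transporter-only"
CAT_RBP_ONLY = "RBP-only"
CAT_NEITHER = "neither"
CATEGORIES = (CAT_BOTH, CAT_TRANSPORTER_ONLY, CAT_RBP_ONLY, CAT_NEITHER)


@dataclass
class CooccurrenceRecord:
    genome: str
    phylum: str
    rbp: bool
    partial_rbp: bool
    families: frozenset
    riboswitch_on_transporter: dict[str, bool] = field(default_factory=dict)
    category: str = CAT_NEITHER


def rbp_status(family_labels, markers: tuple[str, str] = RBP_MARKERS) -> tuple[bool, bool]:
    """(rbp, partial): rbp True iff both marker families are present."""
    present = set(family_labels)
    have = [m for m in markers if m in present]
    return len(have) == len(markers), 0 < len(have) < len(markers)


def detect_rbp(family_labels, markers: tuple[str, str] = RBP_MARKERS) -> bool:
    """True iff both biosynthesis marker families occur among the gene labels."""
    return rbp_status(family_labels, markers)[0]


def _category(rbp: bool, has_transporter: bool) -> str:
    if rbp and has_transporter:
        return CAT_BOTH
    if has_transporter:
        return CAT_TRANSPORTER_ONLY
    if rbp:
        return CAT_RBP_ONLY
    return CAT_NEITHER


def classify_genomes(
    rbp_flags: dict[str, bool],
    calls: list[OrthologCall],
    taxonomy: dict[str, str],
    partial_flags: dict[str, bool] | None = None,
) -> tuple[list[CooccurrenceRecord], dict[str, int]]:
    """Build one record per genome and the four-category tallies.

    Every genome in ``rbp_flags`` is classified; a genome absent from the
    taxonomy table is placed in phylum "unknown" with a logged warning.
    """
    fam_by_genome: dict[str, set[str]] = {}
    ribo_by_genome: dict[str, dict[str, bool]] = {}
    for c in calls:
        fam_by_genome.setdefault(c.genome, set()).add(c.family)
        ribo_by_genome.setdefault(c.genome, {})[c.family] = c.riboswitch_linked

    records = []
    tallies = {cat: 0 for cat in CATEGORIES}
    for genome in sorted(rbp_flags):
        phylum = taxonomy.get(genome)
        if phylum is None:
            log.warning("genome %s missing from taxonomy table; phylum set to 'unknown'", genome)
            phylum = "unknown"
        families = frozenset(fam_by_genome.get(genome, set()))
        rbp = bool(rbp_flags[genome])
        cat = _category(rbp, bool(families))
        tallies[cat] += 1
        records.append(CooccurrenceRecord(
            genome=genome, phylum=phylum, rbp=rbp,
            partial_rbp=bool((partial_flags or {}).get(genome, False)),
            families=families,
            riboswitch_on_transporter=ribo_by_genome.get(genome, {}),
            category=cat,
        ))
    tallies["transporter_total"] = tallies[CAT_BOTH] + tallies[CAT_TRANSPORTER_ONLY]
    tallies["genomes_total"] = len(records)
    return records, tallies


def distribution_matrix(records: list[CooccurrenceRecord], counts: bool = False) -> pd.DataFrame:
    """Phylum x (family, RBP+/-) presence matrix (or genome counts).

    A cell is marked only when at least one genome of that phylum carries the
    family with that RBP status.
    """
    if not records:
        return pd.DataFrame()
    phyla = sorted({r.phylum for r in records})
    families = sorted({f for r in records for f in r.families})
    cols = pd.MultiIndex.from_product([families, ["+", "-"]], names=["family", "RBP"])
    mat = pd.DataFrame(0, index=pd.Index(phyla, name="phylum"), columns=cols)
    for r in records:
        sign = "+" if r.rbp else "-"
        for fam in r.families:
            mat.loc[r.phylum, (fam, sign)] += 1
    return mat if counts else mat.gt(0)


def multi_transporter_report(records: list[CooccurrenceRecord]) -> list[tuple[str, list[str]]]:
    """Genomes carrying two or more transporter families, sorted by genome id."""
    return [(r.genome, sorted(r.families))
            for r in sorted(records, key=lambda r: r.genome)
            if len(r.families) >= 2]


def records_to_tsv(records: list[CooccurrenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tphylum\trbp\tpartial_rbp\tfamilies\triboswitch_on\tcategory\n")
        for r in records:
            fams = ",".join(sorted(r.families))
            ribo = ",".join(f for f in sorted(r.riboswitch_on_transporter)
                            if r.riboswitch_on_transporter[f])
            fh.write(f"{r.genome}\t{r.phylum}\t{int(r.rbp)}\t{int(r.partial_rbp)}\t"
                     f"{fams}\t{ribo}\t{r.category}\n")
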