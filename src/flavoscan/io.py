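"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Bio.SeqIO; GFF3 through gffutils (in-memory database).
The GFF3 dialect is plain ``gene`` features with ``ID`` and optional
``family`` attributes, 1-based inclusive coordinates on disk, converted to
0-based half-open internally.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tu import Gene


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records, width: int = 70) -> None:
    """Write (id, seq) or (id, seq, description) tuples as FASTA."""
    seqrecs = []
    for rec in records:
        rid, seq = rec[0], rec[1]
        desc = rec[2] if len(rec) > 2 else ""
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def write_gff3(path: str | Path, genes: list[Gene], replicon_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in sorted(replicon_lengths):
            fh.write(f"##sequence-region {rep} 1 {replicon_lengths[rep]}\n")
        for g in sorted(genes, key=lambda g: (g.replicon, g.start)):
            attrs = f"ID={g.id}"
            if g.product_family:
                attrs += f";family={g.product_family}"
            fh.write(f"{g.replicon}\tflavoscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")


def read_gff3(path: str | Path) -> dict[str, list[Gene]]:
    """Genes per replicon, sorted by start, with 0-based half-open coordinates."""
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes: dict[str, list[Gene]] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        family = feat.attributes.get("family", [None])[0]
        genes.setdefault(feat.seqid, []).append(Gene(
            id=feat.id, replicon=feat.seqid, start=feat.start - 1, end=feat.end,
            strand=feat.strand, product_family=family,
        ))
    return genes
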