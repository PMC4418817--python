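"""Transcriptional-unit (operon) prediction from gene order and spacing.

Two adjacent genes on the same strand are merged into one transcriptional
unit when their intergenic distance is at most ``d_max`` or when an optional
functional-linkage score (a STRING-like gene-pair score in [0, 1]) is at
least ``link_min``. A strand change always breaks a unit. Overlapping
same-strand genes are treated as distance 0 and therefore merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

DEFAULT_D_MAX = 50
DEFAULT_LINK_MIN = 0.8
DEFAULT_WINDOW = 350


@dataclass(frozen=True)
class Gene:
    """An annotated gene; coordinates are 0-based half-open on the replicon."""

    id: str
    replicon: str
    start: int
    end: int
    strand: str
    product_family: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.id!r}: start must be < end ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-', got {self.strand!r}")


@dataclass
class TranscriptionalUnit:
    """A monocistron or operon: contiguous same-strand genes, in transcription order."""

    id: str
    genes: list[str]
    replicon: str
    strand: str
    span: tuple[int, int]


class LinkageTable:
    """Symmetric gene-pair functional-linkage scores in [0, 1]."""

    def __init__(self, scores: dict[tuple[str, str], float] | None = None):
        self._scores: dict[frozenset, float] = {}
        for (a, b), s in (scores or {}).items():
            self.set(a, b, s)

    def set(self, a: str, b: str, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"linkage score for ({a}, {b}) outside [0, 1]: {score}")
        self._scores[frozenset((a, b))] = score

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        return self._scores.get(frozenset((a, b)), default)

    def __len__(self) -> int:
        return len(self._scores)

    def known_ids(self) -> set[str]:
        out: set[str] = set()
        for pair in self._scores:
            out |= set(pair)
        return out


def predict_tus(
    genes: list[Gene],
    linkage: LinkageTable | None = None,
    d_max: int = DEFAULT_D_MAX,
    link_min: float = DEFAULT_LINK_MIN,
) -> list[TranscriptionalUnit]:
    """Partition one replicon's genes (sorted by start) into transcriptional units."""
    if not genes:
        return []
    replicons = {g.replicon for g in genes}
    if len(replicons) > 1:
        raise ValueError(f"predict_tus expects genes from one replicon, got {sorted(replicons)}")
    starts = [g.start for g in genes]
    if starts != sorted(starts):
        raise ValueError("genes must be sorted by start coordinate")
    if linkage is not None and len(linkage):
        unknown = linkage.known_ids() - {g.id for g in genes}
        if unknown:
            log.warning("linkage table refers to %d unknown gene ids (ignored): %s",
                        len(unknown), sorted(unknown)[:5])

    replicon = genes[0].replicon
    blocks: list[list[Gene]] = [[genes[0]]]
    for prev, cur in zip(genes, genes[1:]):
        same_strand = prev.strand == cur.strand
        gap = max(0, cur.start - prev.end)  # overlap => 0 => merge
        linked = linkage is not None and linkage.get(prev.id, cur.id) >= link_min
        if same_strand and (gap <= d_max or linked):
            blocks[-1].append(cur)
        else:
            blocks.append([cur])

    tus = []
    for i, block in enumerate(blocks):
        strand = block[0].strand
        ordered = [g.id for g in block]
        if strand == "-":
            ordered = ordered[::-1]  # transcription runs right-to-left
        tus.append(TranscriptionalUnit(
            id=f"{replicon}.TU{i}",
            genes=ordered,
            replicon=replicon,
            strand=strand,
            span=(min(g.start for g in block), max(g.end for g in block)),
        ))
    return tus


def upstream_interval(
    tu: TranscriptionalUnit,
    replicon_length: int,
    window: int = DEFAULT_WINDOW,
    circular: bool = False,
) -> list[tuple[int, int]]:
    """Replicon coordinates of the upstream scan window, 5'->3' in transcription order.

    Returns a list of half-open segments (more than one only when a circular
    replicon wraps the origin). For '-' strand units the segments are given in
    genomic orientation; callers reverse-complement the concatenation.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    L = replicon_length
    if tu.strand == "+":
        end = tu.span[0]
        start = end - window
        if start >= 0 or not circular:
            return [(max(0, start), end)] if end > max(0, start) else []
        start %= L
        return [(start, L), (0, end)] if end > 0 else [(start, L)]
    start = tu.span[1]
    end = start + window
    if end <= L or not circular:
        end = min(end, L)
        return [(start, end)] if end > start else []
    end %= L
    return [(start, L), (0, end)] if end > 0 else [(start, L)]


def upstream_region(
    tu: TranscriptionalUnit,
    replicon_seq: str,
    window: int = DEFAULT_WINDOW,
    circular: bool = False,
) -> str:
    """Up to ``window`` nt ending immediately before the unit's first gene.

    Strand-aware: for '-' strand units the 3'-flanking genomic window is
    reverse-complemented so the result reads 5'->3' relative to transcription.
    Truncated at the replicon edge when linear, wrapped when circular. A unit
    at position 0 of a linear replicon yields an empty string.
    """
    segs = upstream_interval(tu, len(replicon_seq), window, circular)
    seq = "".join(replicon_seq[s:e] for s, e in segs)
    if tu.strand == "-":
        seq = reverse_complement(seq)
    return seq
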