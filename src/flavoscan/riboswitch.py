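"""Position-wise log-odds scanning for the FMN riboswitch.

An ungapped profile (bits = log2 of match frequency over background) stands
in for a covariance model: it preserves the bit-score-plus-cutoff contract
of a riboswitch search without secondary-structure scoring. The default
cutoff of 51.34 bits is the calibration rule "lowest score observed on a
riboswitch that regulates a riboflavin biosynthetic operon" applied to the
original anchor set; :func:`calibrate_cutoff` re-derives it from any anchor
set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tu import TranscriptionalUnit, upstream_interval, upstream_region, DEFAULT_WINDOW

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 51.34
BASES = "ACGT"
GAP_CHARS = set("-.")
_FREQ_FLOOR = 1e-9


@dataclass
class ProfileModel:
    """Ungapped nucleotide profile; ``log_odds[p, b]`` in bits vs background."""

    name: str
    log_odds: np.ndarray  # (length, 4), order A C G T
    background: np.ndarray  # (4,)

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError("log_odds must be a (length, 4) matrix")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        freqs = self.background[None, :] * np.exp2(self.log_odds)
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=0.02):
            raise ValueError("implied per-position match distributions do not sum to 1")

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        """Maximum attainable score: sum of per-position maxima."""
        return float(self.log_odds.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# profile\t{self.name}\n")
            fh.write("# background\t" + "\t".join(f"{x:.10g}" for x in self.background) + "\n")
            fh.write("pos\tA\tC\tG\tT\n")
            for p in range(self.length):
                fh.write(str(p) + "\t" + "\t".join(f"{x:.10g}" for x in self.log_odds[p]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileModel":
        name = "profile"
        background = np.full(4, 0.25)
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# profile"):
                    name = line.split("\t", 1)[1]
                elif line.startswith("# background"):
                    background = np.array([float(x) for x in line.split("\t")[1:]])
                elif line and not line.startswith(("#", "pos")):
                    rows.append([float(x) for x in line.split("\t")[1:]])
        return cls(name=name, log_odds=np.array(rows), background=background)


@dataclass(frozen=True)
class RiboswitchHit:
    """A profile match above the bit cutoff, assigned to one transcriptional unit."""

    tu_id: str
    genome: str
    replicon: str
    start: int
    end: int
    strand: str
    score: float


def build_profile(
    training: list[str] | list[tuple[str, str]],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    name: str = "RF00050-lite",
    max_gap_frac: float = 0.5,
) -> ProfileModel:
    """Build a log-odds profile from an aligned set of nucleotide sequences.

    Columns with a gap fraction above ``max_gap_frac`` are dropped; per-base
    frequencies get additive pseudocounts ``(count + pc) / (n + 4 pc)``. With
    pseudocount 0, zero frequencies are floored (rather than -inf) so that the
    profile stays finite.
    """
    seqs = [t[1] if isinstance(t, tuple) else t for t in training]
    if not seqs:
        raise ValueError("empty training alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"training sequences have unequal aligned lengths: {sorted(lengths)}")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)

    cols = np.array([list(s.upper()) for s in seqs])  # (n, L)
    n, L = cols.shape
    gap_frac = np.isin(cols, list(GAP_CHARS)).mean(axis=0)
    kept = np.where(gap_frac <= max_gap_frac)[0]

    log_odds = np.zeros((len(kept), 4))
    for out_p, p in enumerate(kept):
        col = cols[:, p]
        counts = np.array([(col == b).sum() for b in BASES], dtype=float)
        n_valid = counts.sum()
        denom = n_valid + 4 * pseudocount
        if denom == 0:
            raise ValueError(f"column {p} has no countable bases")
        freqs = (counts + pseudocount) / denom
        freqs = np.maximum(freqs, _FREQ_FLOOR)
        log_odds[out_p] = np.log2(freqs / background)
    return ProfileModel(name=name, log_odds=log_odds, background=background)


def score_sequence(profile: ProfileModel, seq: str) -> tuple[float, int]:
    """Best ungapped placement of the profile within ``seq``.

    Returns ``(best_bits, best_offset)``; ties broken by smallest offset.
    Non-ACGT positions contribute 0 bits (the background expectation). A
    sequence shorter than the profile is scored at the single truncated
    placement at offset 0; an empty sequence scores (0.0, 0).
    """
    if not seq:
        return 0.0, 0
    L = profile.length
    lut = {b: i for i, b in enumerate(BASES)}
    idx = np.fromiter((lut.get(c, 4) for c in seq.upper()), dtype=np.int64, count=len(seq))
    lo5 = np.hstack([profile.log_odds, np.zeros((L, 1))])  # column 4: ambiguous => 0 bits
    if len(seq) < L:
        return float(lo5[np.arange(len(seq)), idx].sum()), 0
    w = len(seq) - L + 1
    scores = np.zeros(w)
    for p in range(L):
        scores += lo5[p, idx[p:p + w]]
    best = int(np.argmax(scores))  # first occurrence = smallest offset
    return float(scores[best]), best


def _map_hit(segs: list[tuple[int, int]], strand: str, offset: int, length: int,
             replicon_length: int) -> tuple[int, int]:
    """Map a motif placement inside the concatenated window back to replicon coords."""
    total = sum(e - s for s, e in segs)
    if strand == "+":
        lo = offset
    else:  # sense sequence was the reverse complement of the concatenation
        lo = total - offset - length
    # walk segments to the absolute start
    remaining = lo
    for s, e in segs:
        if remaining < e - s:
            start = s + remaining
            break
        remaining -= e - s
    else:  # pragma: no cover - offset beyond window
        raise ValueError("hit offset outside upstream window")
    # end may exceed the replicon length only for a placement spanning the
    # origin of a circular replicon; coordinates are then read modulo length.
    return start, start + length


def call_riboswitches(
    genomes: dict[str, dict[str, str]],
    tus: dict[str, list[TranscriptionalUnit]],
    profile: ProfileModel,
    cutoff: float = DEFAULT_CUTOFF,
    window: int = DEFAULT_WINDOW,
    circular: bool = False,
    best_only: bool = True,
) -> list[RiboswitchHit]:
    """Scan each unit's upstream window; report placements scoring >= ``cutoff``.

    At most one hit (the best placement) is reported per transcriptional unit
    unless ``best_only`` is False, in which case every placement at or above
    the cutoff is reported.
    """
    hits: list[RiboswitchHit] = []
    for genome in sorted(genomes):
        replicons = genomes[genome]
        for tu in tus.get(genome, []):
            seq = replicons.get(tu.replicon)
            if seq is None:
                raise KeyError(f"replicon {tu.replicon!r} of genome {genome!r} not found")
            region = upstream_region(tu, seq, window=window, circular=circular)
            if not region:
                continue
            segs = upstream_interval(tu, len(seq), window=window, circular=circular)
            if best_only:
                score, offset = score_sequence(profile, region)
                placements = [(score, offset)]
            else:
                L = profile.length
                placements = []
                for off in range(max(1, len(region) - L + 1)):
                    sc, _ = score_sequence(profile, region[off:off + L])
                    placements.append((sc, off))
            for score, offset in placements:
                if score < cutoff:
                    continue
                eff_len = min(profile.length, len(region) - offset)
                start, end = _map_hit(segs, tu.strand, offset, eff_len, len(seq))
                hits.append(RiboswitchHit(
                    tu_id=tu.id, genome=genome, replicon=tu.replicon,
                    start=start, end=end, strand=tu.strand, score=score,
                ))
    return hits


def calibrate_cutoff(anchor_scores) -> float:
    """Lowest bit score over an anchor set of true-positive riboswitches."""
    scores = list(anchor_scores)
    if not scores:
        raise ValueError("cannot calibrate a cutoff from an empty anchor set")
    return float(min(scores))


def hits_to_tsv(hits: list[RiboswitchHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\treplicon\ttu_id\tstart\tend\tstrand\tscore\n")
        for h in hits:
            fh.write(f"{h.genome}\t{h.replicon}\t{h.tu_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.score:.4f}\n")


def hits_to_bed(hits: list[RiboswitchHit], path: str | Path) -> None:
    """BED6, 0-based half-open, score column in bits."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.replicon}\t{h.start}\t{h.end}\t{h.tu_id}\t{h.score:.4f}\t{h.strand}\n")
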