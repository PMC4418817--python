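"""Prototype-anchored transporter orthology.

Candidates are accepted for a family when their local-alignment identity to
the family prototype is strictly greater than the family's identity floor
("more than 38% identical") and prototype coverage is at least the coverage
floor ("80% or more"). The RfnT family uses the stricter 42%/90% rule.
Borderline candidates — identity within a configured margin below the floor
— are accepted only when their transcriptional unit carries a riboswitch
hit, mirroring the evidence-based threshold adjustment; such acceptances are
flagged, never silent.

Bi-directional best hits and Markov clustering of the similarity graph
provide the supporting evidence recorded on each call. Composite systems
(RibXY, ECF-RibU, RfuABCD) are represented by their substrate-binding
component only (RibY, RibU, RfuA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentResult, align_local
from .riboswitch import RiboswitchHit
from .tu import TranscriptionalUnit

FAMILIES = ("ImpX", "RfnT", "RibZ", "RibV", "RibM", "RibN", "RibY", "RibU", "RfuA")
DEFAULT_IDENTITY_MIN = 0.38
DEFAULT_COVERAGE_MIN = 0.80
RFNT_IDENTITY_MIN = 0.42
RFNT_COVERAGE_MIN = 0.90


@dataclass(frozen=True)
class FamilyPrototype:
    """The reference protein of one transporter family plus its acceptance floors."""

    family: str
    sequence: str
    identity_min: float = DEFAULT_IDENTITY_MIN
    coverage_min: float = DEFAULT_COVERAGE_MIN

    def __post_init__(self):
        if not 0.0 < self.identity_min <= 1.0 or not 0.0 < self.coverage_min <= 1.0:
            raise ValueError(f"prototype {self.family!r}: thresholds must lie in (0, 1]")


def make_prototypes(sequences: dict[str, str]) -> list[FamilyPrototype]:
    """Wrap family->sequence with the standard thresholds (RfnT stricter)."""
    out = []
    for fam in sorted(sequences):
        if fam == "RfnT":
            out.append(FamilyPrototype(fam, sequences[fam], RFNT_IDENTITY_MIN, RFNT_COVERAGE_MIN))
        else:
            out.append(FamilyPrototype(fam, sequences[fam]))
    return out


@dataclass
class OrthologCall:
    genome: str
    gene_id: str
    family: str
    identity: float
    coverage: float
    bdbh: bool = False
    cluster: str | None = None
    riboswitch_linked: bool = False
    threshold_override: bool = False  # accepted below the floor on riboswitch evidence


def best_hits(proteome_a: dict[str, str], proteome_b: dict[str, str],
              **align_kw) -> dict[str, str | None]:
    """Best subject in B per query in A (by score; ties -> smallest subject id).

    Queries with no alignment scoring above 0 map to None (hitless).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("best_hits requires two non-empty proteomes")
    out: dict[str, str | None] = {}
    for q in proteome_a:
        best_id, best_score = None, 0.0
        for s in sorted(proteome_b):
            r = align_local(proteome_a[q], proteome_b[s], query_id=q, subject_id=s, **align_kw)
            if r.score > best_score:
                best_id, best_score = s, r.score
        out[q] = best_id
    return out


def bdbh(proteome_a: dict[str, str], proteome_b: dict[str, str], **align_kw) -> set[tuple[str, str]]:
    """Reciprocal pairs: (a, b) with best(a->B) = b and best(b->A) = a."""
    fwd = best_hits(proteome_a, proteome_b, **align_kw)
    rev = best_hits(proteome_b, proteome_a, **align_kw)
    return {(a, b) for a, b in fwd.items() if b is not None and rev.get(b) == a}


def cluster_similarity_graph(
    edges,
    inflation: float = 2.0,
    nodes=None,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
    self_loop: float = 1.0,
) -> list[frozenset]:
    """Markov clustering of a weighted similarity graph.

    ``edges`` is an iterable of (u, v, weight > 0); ``nodes`` may add isolated
    nodes (preserved as singleton clusters). Returns disjoint clusters sorted
    by their smallest member. Expansion is matrix power 2 by default; the
    inflation exponent controls granularity; entries below ``prune`` are
    zeroed between iterations.
    """
    edge_list = [(u, v, float(w)) for u, v, w in edges]
    for u, v, w in edge_list:
        if w <= 0:
            raise ValueError(f"non-positive edge weight on ({u!r}, {v!r}): {w}")
    names = sorted({n for u, v, _ in edge_list for n in (u, v)} | set(nodes or []))
    if not names:
        return []
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    M = np.zeros((n, n))
    for u, v, w in edge_list:
        i, j = index[u], index[v]
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    np.fill_diagonal(M, np.maximum(M.diagonal(), self_loop))
    M = M / M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - prev).max() < tol:
            break

    # attractor interpretation: assign each node to the cluster of the row
    # (attractor) holding its largest stationary mass; deterministic by index.
    owner = M.argmax(axis=0)
    # merge attractors that share members (overlapping attractor systems)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n):
        i = int(owner[j])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, set[str]] = {}
    for j in range(n):
        groups.setdefault(find(j), set()).add(names[j])
    return sorted((frozenset(g) for g in groups.values()), key=lambda s: min(s))


def _tu_of_gene(tus: dict[str, list[TranscriptionalUnit]] | None) -> dict[tuple[str, str], str]:
    out: dict[tuple[str, str], str] = {}
    for genome, units in (tus or {}).items():
        for tu in units:
            for gid in tu.genes:
                out[(genome, gid)] = tu.id
    return out


def call_orthologs(
    proteomes: dict[str, dict[str, str]],
    prototypes: list[FamilyPrototype],
    riboswitch_hits: list[RiboswitchHit] | None = None,
    tus: dict[str, list[TranscriptionalUnit]] | None = None,
    margin: float = 0.05,
    coverage_on: str = "subject",
    with_bdbh: bool = True,
    clusters: list[frozenset] | None = None,
    **align_kw,
) -> list[OrthologCall]:
    """Assign candidate proteins to transporter families against the prototypes.

    A gene passing the floors for two families keeps the higher-identity
    family (ties broken alphabetically). ``margin`` is the identity band below
    the floor within which riboswitch evidence on the gene's transcriptional
    unit rescues a candidate (flagged as an override).
    """
    if not prototypes:
        raise ValueError("prototype list is empty")
    gene_tu = _tu_of_gene(tus)
    ribo_tus = {(h.genome, h.tu_id) for h in (riboswitch_hits or [])}
    cluster_of: dict[str, str] = {}
    for c in clusters or []:
        label = f"cluster_{min(c)}"
        for member in c:
            cluster_of[member] = label

    calls: list[OrthologCall] = []
    for genome in sorted(proteomes):
        proteome = proteomes[genome]
        # alignment matrix gene x prototype, reused for BDBH evidence
        results: dict[str, dict[str, AlignmentResult]] = {}
        for gid in sorted(proteome):
            results[gid] = {
                p.family: align_local(proteome[gid], p.sequence, query_id=gid,
                                      subject_id=p.family, coverage_on=coverage_on, **align_kw)
                for p in prototypes
            }
        # best family per gene / best gene per family (for the BDBH flag)
        best_fam: dict[str, str | None] = {}
        for gid, row in results.items():
            fams = sorted(row)
            scores = [row[f].score for f in fams]
            best = max(scores) if scores else 0.0
            best_fam[gid] = fams[int(np.argmax(scores))] if best > 0 else None
        best_gene: dict[str, str | None] = {}
        for p in prototypes:
            gids = sorted(results)
            scores = [results[g][p.family].score for g in gids]
            best = max(scores) if scores else 0.0
            best_gene[p.family] = gids[int(np.argmax(scores))] if best > 0 else None

        for gid in sorted(proteome):
            accepted: list[tuple[float, str, AlignmentResult, bool]] = []
            tu_id = gene_tu.get((genome, gid))
            linked = tu_id is not None and (genome, tu_id) in ribo_tus
            for p in prototypes:
                r = results[gid][p.family]
                if r.coverage < p.coverage_min:
                    continue
                if r.identity > p.identity_min:
                    accepted.append((r.identity, p.family, r, False))
                elif linked and r.identity > p.identity_min - margin:
                    accepted.append((r.identity, p.family, r, True))
            if not accepted:
                continue
            accepted.sort(key=lambda t: (-t[0], t[1]))
            identity, family, r, override = accepted[0]
            is_bdbh = with_bdbh and best_fam[gid] == family and best_gene[family] == gid
            calls.append(OrthologCall(
                genome=genome, gene_id=gid, family=family,
                identity=identity, coverage=r.coverage,
                bdbh=is_bdbh, cluster=cluster_of.get(gid),
                riboswitch_linked=linked, threshold_override=override,
            ))
    return calls


def count_tryptophans(seq: str) -> int:
    """Number of tryptophan (W) residues; a heterologous-expression feasibility check."""
    return seq.upper().count("W")
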