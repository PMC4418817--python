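"""End-to-end orchestration: synth -> TUs -> riboswitch scan -> orthology ->
co-occurrence -> tree, with a run manifest and truth-table evaluation.

A run is driven by one YAML/dict config with a ``cohort`` section (either an
explicit :class:`~flavoscan.synthetic.CohortConfig` mapping or a ``random``
block for :func:`~flavoscan.synthetic.random_cohort_config`) and a ``params``
section holding every stage threshold. All parameters are echoed in the
manifest together with per-file checksums, so a rerun with an identical
config reproduces identical checksums for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml

from . import io as fio
from .cooccurrence import classify_genomes, distribution_matrix, multi_transporter_report, \
    records_to_tsv, rbp_status
from .orthology import OrthologCall, call_orthologs, cluster_similarity_graph, align_local
from .phylo import bootstrap_support, distance_matrix, mask_columns, nj_tree
from .riboswitch import DEFAULT_CUTOFF, call_riboswitches, calibrate_cutoff, hits_to_bed, \
    hits_to_tsv
from .synthetic import Cohort, CohortConfig, TruthTable, generate_cohort, random_cohort_config
from .tu import DEFAULT_D_MAX, DEFAULT_LINK_MIN, DEFAULT_WINDOW, predict_tus

DEFAULT_PARAMS = {
    "d_max": DEFAULT_D_MAX,
    "link_min": DEFAULT_LINK_MIN,
    "window": DEFAULT_WINDOW,
    "cutoff": DEFAULT_CUTOFF,
    "identity_min": 0.38,
    "coverage_min": 0.80,
    "rfnt_identity": 0.42,
    "rfnt_coverage": 0.90,
    "inflation": 2.0,
    "margin": 0.05,
    "bootstrap": 0,
    "tree_seed": 42,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "cohort" not in config:
        raise ValueError("run config must be a mapping with a 'cohort' section")
    return config


def _cohort_config(config: dict) -> CohortConfig:
    section = config["cohort"]
    if not isinstance(section, dict):
        raise ValueError("'cohort' section must be a mapping")
    if "random" in section:
        return random_cohort_config(**section["random"])
    return CohortConfig.from_dict(section)


def calls_to_tsv(calls: list[OrthologCall], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tgene_id\tfamily\tidentity\tcoverage\tbdbh\tcluster\t"
                 "riboswitch_linked\tthreshold_override\n")
        for c in calls:
            fh.write(f"{c.genome}\t{c.gene_id}\t{c.family}\t{c.identity:.6f}\t"
                     f"{c.coverage:.6f}\t{int(c.bdbh)}\t{c.cluster or ''}\t"
                     f"{int(c.riboswitch_linked)}\t{int(c.threshold_override)}\n")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage; returns a summary dict (paths, tallies, metrics)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        raise ValueError(f"unknown params: {sorted(unknown)}")

    cohort_cfg = _cohort_config(config)
    decisions: list[str] = []

    # stage 1: synthetic cohort
    cohort, truth = generate_cohort(cohort_cfg, out / "cohort")

    # stage 2: transcriptional units
    tus = {}
    for genome in sorted(cohort.genes):
        tus[genome] = predict_tus(cohort.genes[genome], d_max=params["d_max"],
                                  link_min=params["link_min"])
    with open(out / "tus.tsv", "w") as fh:
        fh.write("genome\ttu_id\treplicon\tstrand\tstart\tend\tgenes\n")
        for genome in sorted(tus):
            for tu in tus[genome]:
                fh.write(f"{genome}\t{tu.id}\t{tu.replicon}\t{tu.strand}\t"
                         f"{tu.span[0]}\t{tu.span[1]}\t{','.join(tu.genes)}\n")

    # stage 3: riboswitch scan
    hits = call_riboswitches(cohort.genomes, tus, cohort.profile,
                             cutoff=params["cutoff"], window=params["window"])
    hits_to_tsv(hits, out / "riboswitch_hits.tsv")
    hits_to_bed(hits, out / "riboswitch_hits.bed")

    # cutoff re-calibration from biosynthesis-operon anchors (reported, not applied)
    marker_tus = set()
    for genome, units in tus.items():
        fam_of = {g.id: g.product_family for g in cohort.genes[genome]}
        for tu in units:
            fams = {fam_of.get(g) for g in tu.genes}
            if {"COG0054", "COG0307"} & fams:
                marker_tus.add((genome, tu.id))
    anchor_scores = [h.score for h in hits if (h.genome, h.tu_id) in marker_tus]
    calibrated = calibrate_cutoff(anchor_scores) if anchor_scores else None
    if calibrated is not None:
        decisions.append(f"cutoff calibration: min anchor score {calibrated:.2f} bits "
                         f"over {len(anchor_scores)} biosynthesis-operon riboswitches "
                         f"(configured cutoff {params['cutoff']} kept)")

    # stage 4: orthology
    prototypes = [
        p if p.family != "RfnT" else type(p)(p.family, p.sequence,
                                             params["rfnt_identity"], params["rfnt_coverage"])
        for p in cohort.prototypes
    ]
    prototypes = [
        p if p.family == "RfnT" else type(p)(p.family, p.sequence,
                                             params["identity_min"], params["coverage_min"])
        for p in prototypes
    ]
    # similarity graph: candidate-vs-prototype edges weighted by score over self-score
    edges = []
    nodes = []
    proto_self = {p.family: align_local(p.sequence, p.sequence).score for p in prototypes}
    for genome in sorted(cohort.proteomes):
        for gid, seq in sorted(cohort.proteomes[genome].items()):
            nodes.append(gid)
            for p in prototypes:
                r = align_local(seq, p.sequence, query_id=gid, subject_id=p.family)
                w = r.score / proto_self[p.family]
                if w > 0.05:
                    edges.append((gid, p.family, w))
    clusters = cluster_similarity_graph(edges, inflation=params["inflation"],
                                        nodes=nodes + [p.family for p in prototypes])
    calls = call_orthologs(cohort.proteomes, prototypes, riboswitch_hits=hits, tus=tus,
                           margin=params["margin"], clusters=clusters)
    for c in calls:
        if c.threshold_override:
            decisions.append(f"riboswitch-linked acceptance below identity floor: "
                             f"{c.genome}/{c.gene_id} -> {c.family} at {c.identity:.3f}")
    calls_to_tsv(calls, out / "ortholog_calls.tsv")

    # stage 5: co-occurrence
    rbp_flags, partial = {}, {}
    for genome in sorted(cohort.genes):
        labels = [g.product_family for g in cohort.genes[genome] if g.product_family]
        rbp_flags[genome], partial[genome] = rbp_status(labels)
    records, tallies = classify_genomes(rbp_flags, calls, cohort.taxonomy, partial)
    records_to_tsv(records, out / "cooccurrence_records.tsv")
    matrix = distribution_matrix(records)
    matrix.astype(int).to_csv(out / "distribution_matrix.tsv", sep="\t")
    multi = multi_transporter_report(records)
    with open(out / "summary.json", "w") as fh:
        json.dump({
            "tallies": tallies,
            "calibrated_cutoff": calibrated,
            "multi_transporter_genomes": [[g, fams] for g, fams in multi],
            "decisions": decisions,
        }, fh, indent=2, sort_keys=True)

    # stage 6: display phylogeny from the cohort marker alignment
    tree_path = out / "tree.nwk"
    if len(cohort.marker_alignment) >= 3:
        if params["bootstrap"] > 0:
            tree = bootstrap_support(cohort.marker_alignment, params["bootstrap"],
                                     seed=params["tree_seed"])
        else:
            tree = nj_tree(distance_matrix(mask_columns(cohort.marker_alignment)))
        tree.write(path=str(tree_path), schema="newick")
    else:
        tree_path.write_text("")

    # manifest
    stage_files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": _config_hash(config),
        "seed": cohort_cfg.seed,
        "params": params,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in stage_files},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    metrics = evaluate_against_truth(out, truth,
                                     identity_min=params["identity_min"],
                                     coverage_min=params["coverage_min"],
                                     rfnt_identity=params["rfnt_identity"],
                                     rfnt_coverage=params["rfnt_coverage"])
    with open(out / "evaluation.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    return {"out_dir": str(out), "tallies": tallies, "metrics": metrics,
            "calibrated_cutoff": calibrated, "n_hits": len(hits), "n_calls": len(calls)}


def _read_tsv(path: Path) -> list[dict]:
    import csv
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def evaluate_against_truth(out_dir: str | Path, truth: TruthTable | None = None,
                           identity_min: float = 0.38, coverage_min: float = 0.80,
                           rfnt_identity: float = 0.42, rfnt_coverage: float = 0.90) -> dict:
    """Score a synthetic run against its planted truth.

    Returns riboswitch recall/precision, ortholog-call accuracy (agreement of
    the call set with the truth-expected set under the same thresholds) and
    per-genome category accuracy, all in [0, 1], plus confusion detail.
    """
    out = Path(out_dir)
    if truth is None:
        truth = TruthTable.from_dir(out / "cohort" / "truth")

    hits = _read_tsv(out / "riboswitch_hits.tsv")
    hit_keys = {(h["genome"], h["tu_id"]) for h in hits}
    truth_keys = {(p.genome, p.tu_id) for p in truth.planted_riboswitches}
    run_genomes = {r["genome"] for r in _read_tsv(out / "cooccurrence_records.tsv")}
    if not truth.rbp_status and run_genomes:
        raise ValueError("truth table is empty but the run contains genomes")
    if truth.rbp_status and set(truth.rbp_status) != run_genomes:
        raise ValueError("truth/output genome sets differ: "
                         f"{sorted(set(truth.rbp_status) ^ run_genomes)[:5]}")

    recall = (len(hit_keys & truth_keys) / len(truth_keys)) if truth_keys else 1.0
    precision = (len(hit_keys & truth_keys) / len(hit_keys)) if hit_keys else 1.0

    def floors(fam: str) -> tuple[float, float]:
        return (rfnt_identity, rfnt_coverage) if fam == "RfnT" else (identity_min, coverage_min)

    expected = set()
    for p in truth.planted_orthologs:
        i_min, c_min = floors(p.family)
        if p.realized_identity > i_min and p.realized_coverage >= c_min:
            expected.add((p.genome, p.gene_id, p.family))
    called = {(c["genome"], c["gene_id"], c["family"])
              for c in _read_tsv(out / "ortholog_calls.tsv")}
    union = expected | called
    ortholog_accuracy = (len(expected & called) / len(union)) if union else 1.0

    expected_fams: dict[str, set] = {g: set() for g in truth.rbp_status}
    for g, _, fam in expected:
        expected_fams[g].add(fam)
    correct = 0
    confusion = []
    records = {r["genome"]: r for r in _read_tsv(out / "cooccurrence_records.tsv")}
    for g, rbp in truth.rbp_status.items():
        has_t = bool(expected_fams[g])
        want = ("RBP+transporter" if rbp and has_t else
                "transporter-only" if has_t else
                "RBP-only" if rbp else "neither")
        got = records[g]["category"]
        correct += want == got
        if want != got:
            confusion.append({"genome": g, "expected": want, "observed": got})
    category_accuracy = correct / len(truth.rbp_status) if truth.rbp_status else 1.0

    return {
        "riboswitch_recall": recall,
        "riboswitch_precision": precision,
        "ortholog_accuracy": ortholog_accuracy,
        "category_accuracy": category_accuracy,
        "n_planted_riboswitches": len(truth_keys),
        "n_riboswitch_hits": len(hit_keys),
        "n_expected_orthologs": len(expected),
        "n_ortholog_calls": len(called),
        "category_confusion": confusion,
    }
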