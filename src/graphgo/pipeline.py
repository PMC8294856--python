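"""End-to-end orchestration: load a data directory, build the benchmark split
and feature space, train models, score test proteins with any method, and
evaluate. The CLI module is a thin wrapper around these functions."""

from __future__ import annotations

import json
import time
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import baselines, evaluation, gnn, synthetic
from .features import SignatureMatrix, build_vocabulary, read_interproscan_tsv, vectorize
from .graph import ProteinGraph, load_string_edges, normalized_adjacency, top_k_prune
from .homology import HomologyTable, read_homology_tsv
from .ontology import (
    AnnotationTable,
    BenchmarkSplit,
    Ontology,
    load_obo,
    make_time_split,
    read_annotation_tsv,
    select_scored_terms,
)
from .scores import ScoreMatrix

logger = logging.getLogger(__name__)

METHODS = ("deepgraphgo", "blast-knn", "net-knn", "lr-interpro", "dnn-interpro")


class DataError(RuntimeError):
    """Raised when inputs are missing or structurally unusable."""


@dataclass
class Dataset:
    """Everything one GO domain's run needs, aligned and ready."""

    ontology: Ontology
    graph: ProteinGraph
    homology: HomologyTable
    features: SignatureMatrix
    split: BenchmarkSplit
    train_table: AnnotationTable
    test_table: AnnotationTable
    domain: str


def load_dataset(data_dir, domain: str = "BPO", t0=synthetic.T0, t1=synthetic.T1,
                 valid_window=synthetic.VALID_WINDOW, min_train_count: int = 0) -> Dataset:
    """Read a fixture directory (ontology.obo, annotations.tsv, interproscan.tsv,
    network.tsv, homology.tsv) and assemble the aligned dataset."""
    d = Path(data_dir)
    required = ["ontology.obo", "annotations.tsv", "interproscan.tsv",
                "network.tsv", "homology.tsv"]
    missing = [f for f in required if not (d / f).exists()]
    if missing:
        raise DataError(f"missing input files in {d}: {', '.join(missing)}")
    with open(d / "ontology.obo") as f:
        ontology = load_obo(f)
    with open(d / "annotations.tsv") as f:
        records = read_annotation_tsv(f)
    with open(d / "network.tsv") as f:
        graph = load_string_edges(f)
    with open(d / "homology.tsv") as f:
        homology = read_homology_tsv(f)
    with open(d / "interproscan.tsv") as f:
        hits = read_interproscan_tsv(f)
    return assemble_dataset(ontology, records, graph, homology, hits, domain,
                            t0, t1, valid_window, min_train_count)


def assemble_dataset(ontology, records, graph, homology, hits, domain="BPO",
                     t0=synthetic.T0, t1=synthetic.T1, valid_window=synthetic.VALID_WINDOW,
                     min_train_count: int = 0) -> Dataset:
    split = make_time_split(records, ontology, domain, t0, t1, valid_window=valid_window)
    train_table = select_scored_terms(split.train, min_train_count)
    test_table = split.test.restrict_terms(train_table.terms)
    # feature space: vocabulary from training and network proteins; rows for
    # every protein the run can touch
    vocab_proteins = list(dict.fromkeys(list(graph.nodes) + train_table.proteins))
    vocab = build_vocabulary(hits, vocab_proteins)
    all_proteins = list(dict.fromkeys(
        list(graph.nodes) + train_table.proteins
        + (split.valid.proteins if split.valid else []) + test_table.proteins))
    features = vectorize(hits, vocab, all_proteins)
    return Dataset(ontology=ontology, graph=graph, homology=homology,
                   features=features, split=split, train_table=train_table,
                   test_table=test_table, domain=domain)


def dataset_from_benchmark(bench: synthetic.SynthBenchmark,
                           min_train_count: int = 0) -> Dataset:
    """Assemble a Dataset directly from an in-memory synthetic benchmark."""
    return assemble_dataset(bench.ontology, bench.records, bench.graph,
                            bench.homology, bench.hits, bench.config.domain,
                            min_train_count=min_train_count)


def train_models(ds: Dataset, config: gnn.TrainConfig | None = None, base_seed: int = 0,
                 method: str = "deepgraphgo") -> list:
    """Train the ensemble (or the graph-free ablation) on the dataset."""
    config = config or gnn.TrainConfig()
    t_start = time.perf_counter()
    if method == "dnn-interpro":
        models = [gnn.train(ds.features, None, ds.train_table, ds.split.valid,
                            config, seed=base_seed + int(s), extra_fc=True)[0]
                  for s in config.seeds]
    elif method == "deepgraphgo":
        pruned = top_k_prune(ds.graph, config.k_edges)
        normalized = normalized_adjacency(pruned)
        models = gnn.train_ensemble(ds.features, normalized, ds.train_table,
                                    ds.split.valid, config, base_seed=base_seed)
    else:
        raise ValueError(f"method {method} does not train a neural model")
    logger.info("trained %d %s models in %.1fs", len(models), method,
                time.perf_counter() - t_start)
    return models


def predict_method(ds: Dataset, method: str, models: Sequence[gnn.GnnModel] | None = None,
                   proteins: Sequence[str] | None = None,
                   config: gnn.TrainConfig | None = None) -> ScoreMatrix:
    """Score ``proteins`` (default: the test set) with one of the five methods."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    proteins = list(proteins if proteins is not None else ds.test_table.proteins)
    config = config or gnn.TrainConfig()
    if method == "blast-knn":
        return baselines.blast_knn_score(proteins, ds.homology, ds.train_table)
    if method == "net-knn":
        return baselines.net_knn_score(proteins, ds.graph, ds.train_table, ds.homology)
    if method == "lr-interpro":
        model = baselines.lr_train(ds.features, ds.train_table)
        return baselines.lr_predict(model, ds.features, proteins)
    if models is None:
        raise ValueError(f"method {method} needs trained models")
    if method == "dnn-interpro":
        return gnn.predict_ensemble(models, ds.features, None, proteins)
    pruned = top_k_prune(ds.graph, config.k_edges)
    normalized = normalized_adjacency(pruned)
    return gnn.predict_ensemble(models, ds.features, normalized, proteins, ds.homology)


def evaluate_predictions(ds: Dataset, predictions: dict, bootstrap_pairs=(),
                         n_resamples: int = 100, seed: int = 0) -> dict:
    """Fmax / AUPR / M-AUPR per method, overall and per coverage stratum,
    plus optional bootstrap comparisons of named method pairs."""
    truth = ds.test_table
    strata = evaluation.stratify_coverage(truth.proteins, ds.graph.nodes, ds.homology)
    report: dict = {"n_test": truth.n_proteins, "methods": {}, "strata_sizes": {}}
    for s in ("STRI", "HOMO", "NONE"):
        report["strata_sizes"][s] = sum(1 for v in strata.values() if v == s)
    for name, sm in predictions.items():
        entry = {}
        res = evaluation.fmax(sm, truth)
        entry["fmax"] = res.fmax
        entry["tau_star"] = res.tau_star
        entry["aupr"] = evaluation.aupr_pairs(sm, truth)
        try:
            entry["m_aupr"] = evaluation.m_aupr(sm, truth)
        except ValueError:
            entry["m_aupr"] = None
        per_stratum = {}
        for s in ("STRI", "HOMO", "NONE"):
            members = [p for p in truth.proteins if strata[p] == s]
            if not members:
                continue
            sub_truth = AnnotationTable(
                members, truth.terms,
                truth.dense()[[truth.proteins.index(p) for p in members]])
            try:
                per_stratum[s] = evaluation.fmax(sm, sub_truth).fmax
            except ValueError:
                per_stratum[s] = None
        entry["fmax_by_stratum"] = per_stratum
        report["methods"][name] = entry
    comparisons = {}
    for a, b in bootstrap_pairs:
        res = evaluation.bootstrap_compare(predictions[a], predictions[b], truth,
                                           n_resamples=n_resamples, seed=seed)
        comparisons[f"{a} vs {b}"] = {
            "mean_fmax_difference": res.mean_difference,
            "p_value": res.p_value,
            "degenerate": res.degenerate,
        }
    if comparisons:
        report["bootstrap"] = comparisons
    return report


def write_report(report: dict, path):
    with open(path, "w") as f:
        json.dump(report, f, indent=2)


def format_report(report: dict) -> str:
    lines = [f"benchmark proteins: {report['n_test']}  "
             f"(STRI {report['strata_sizes'].get('STRI', 0)}, "
             f"HOMO {report['strata_sizes'].get('HOMO', 0)}, "
             f"NONE {report['strata_sizes'].get('NONE', 0)})",
             f"{'method':<14} {'Fmax':>6} {'AUPR':>6} {'M-AUPR':>7}"]
    for name, e in report["methods"].items():
        m_aupr = f"{e['m_aupr']:.3f}" if e["m_aupr"] is not None else "   -"
        lines.append(f"{name:<14} {e['fmax']:>6.3f} {e['aupr']:>6.3f} {m_aupr:>7}")
    for key, c in report.get("bootstrap", {}).items():
        lines.append(f"{key}: ΔFmax={c['mean_fmax_difference']:+.3f}  p={c['p_value']:.3g}")
    return "\n".join(lines)
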