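"""Self-contained synthetic benchmarks.

Generates everything the pipeline consumes — a DAG-structured label space, a
sparse binary signature matrix predictive of labels, a label-homophilous
weighted protein network, a pairwise homology table and time-stamped
annotations — at desk scale, in the same on-disk formats as the real inputs
(OBO, TSVs), so the command-line paths are identical for real and synthetic
data.

Two signal channels are dialled independently:

* feature signal ``s_f``: each leaf term is linked to a few signatures; a
  protein carrying a linked signature gets ``s_f * 15`` added to that term's
  log-odds. High ``s_f`` makes feature-only methods strong.
* network signal ``s_n``: after base labels are drawn, each protein copies
  each base term of one random network neighbor with probability ``s_n``.
  Those copied terms are invisible to a protein's own features but visible to
  its neighbors' — the regime where graph convolution pays off.

Homology bit-scores are proportional to shared-signature counts, so homologs
have correlated labels, and percent identity grows with sharing.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import features as feat
from .graph import ProteinGraph, write_string_edges
from .homology import HomologyTable, write_homology_tsv
from .ontology import (
    AnnotationRecord,
    BenchmarkSplit,
    Ontology,
    make_time_split,
    write_annotation_tsv,
)

#: log-odds added per linked signature, at full feature signal (s_f = 1).
FEATURE_EFFECT_SCALE = 15.0

_EVIDENCE_POOL = ("IDA", "IMP", "EXP", "IGI", "IEP", "IC", "TAS")

TRAIN_DATE = _dt.date(2017, 6, 15)
VALID_DATE = _dt.date(2018, 6, 15)
TEST_DATE = _dt.date(2019, 6, 15)
VALID_WINDOW = (_dt.date(2018, 1, 1), _dt.date(2019, 1, 1))
T0 = _dt.date(2019, 1, 1)
T1 = _dt.date(2020, 1, 1)


@dataclass
class SynthConfig:
    """Generator knobs. Defaults are the desk-scale study conditions:
    300 proteins over 3 species, a 60-term single-domain DAG, 120 signatures,
    mean network degree 10, and a network-signal-dominated labelling
    (s_n = 0.6, s_f = 0.2)."""

    n_proteins: int = 300
    n_terms: int = 60
    n_signatures: int = 120
    dag_depth: int = 4
    mean_degree: float = 10.0
    homophily: float = 0.5          # β: edge-probability boost per shared term
    feature_signal: float = 0.2     # s_f
    network_signal: float = 0.6     # s_n
    label_density: float = 0.05     # base leaf-term rate
    sigs_per_protein: float = 8.0   # mean signatures per protein
    sigs_per_term: int = 3          # signatures linked to each leaf term
    n_species: int = 3
    test_fraction: float = 0.2
    valid_fraction: float = 0.1
    offnet_fraction: float = 0.05   # test proteins left out of the network
    domain: str = "BPO"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_proteins, self.n_terms, self.n_signatures, self.dag_depth,
               self.n_species) < 1:
            raise ValueError("all counts must be positive")
        for name in ("homophily", "network_signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SynthBenchmark:
    """A generated benchmark plus its provenance (config + seed); regeneration
    from the provenance is bit-identical."""

    ontology: Ontology
    hits: dict
    signatures: feat.SignatureMatrix
    graph: ProteinGraph
    homology: HomologyTable
    records: list
    split: BenchmarkSplit
    species: dict
    base_terms: dict
    config: SynthConfig

    @property
    def provenance(self) -> dict:
        return {"config": asdict(self.config)}


def _term_id(i: int) -> str:
    return f"GO:9{i:06d}"


def generate_dag(n_terms: int, depth: int, seed: int, domain: str = "BPO") -> Ontology:
    """Layered random DAG: one root, every non-root term gets 1–2 parents from
    the layer above."""
    rng = np.random.default_rng(seed)
    root = _term_id(0)
    parents = {root: set()}
    domains = {root: domain}
    layers = [[root]]
    remaining = n_terms - 1
    for level in range(1, depth + 1):
        if remaining <= 0:
            break
        left = depth - level
        size = remaining if left == 0 else max(1, round(remaining / (left + 1)))
        layer = []
        for _ in range(size):
            tid = _term_id(n_terms - remaining)
            remaining -= 1
            above = layers[-1]
            n_par = 1 if len(above) == 1 else int(rng.integers(1, 3))
            chosen = rng.choice(len(above), size=min(n_par, len(above)), replace=False)
            parents[tid] = {above[int(c)] for c in chosen}
            domains[tid] = domain
            layer.append(tid)
        layers.append(layer)
    return Ontology(parents, domains)


def _leaf_terms(ontology: Ontology) -> list:
    has_child = set()
    for t, ps in ontology.parents.items():
        has_child |= ps
    return sorted(ontology.terms - has_child)


def generate_proteins(config: SynthConfig, rng: np.random.Generator | None = None):
    """Proteins partitioned into species, sparse signature draws, and a
    homology table between proteins sharing >= 2 signatures (bit-score and
    percent identity increase with the shared count)."""
    rng = rng or np.random.default_rng(config.seed)
    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]
    species = {p: f"sp{i % config.n_species}" for i, p in enumerate(proteins)}
    sig_names = [f"IPR9{j:05d}" for j in range(config.n_signatures)]
    hits: dict[str, set] = {}
    for p in proteins:
        k = 1 + rng.poisson(config.sigs_per_protein - 1)
        k = min(k, config.n_signatures)
        chosen = rng.choice(config.n_signatures, size=k, replace=False)
        hits[p] = {sig_names[int(j)] for j in chosen}
    homology = HomologyTable()
    for i, p in enumerate(proteins):
        for q in proteins[i + 1:]:
            shared = len(hits[p] & hits[q])
            if shared < 2:
                continue
            bit = 25.0 * shared + float(rng.uniform(0, 10))
            ident = float(np.clip(20.0 + 15.0 * shared + rng.normal(0, 5), 10.0, 99.9))
            ev = 10.0 ** (-float(shared))
            homology.add(p, q, bit, ev, ident)
            homology.add(q, p, bit, ev, ident)
    vocab = feat.build_vocabulary(hits, proteins)
    matrix = feat.vectorize(hits, vocab, proteins)
    return matrix, hits, homology, species


def _assign_base_terms(config: SynthConfig, ontology: Ontology, hits: dict,
                       proteins: list, rng: np.random.Generator) -> tuple[dict, dict]:
    """Draw each protein's base leaf-term set from its signatures.

    Leaf-term log-odds = logit(label_density) + s_f·15 per linked signature.
    Every protein ends up with at least one leaf term.
    """
    leaves = _leaf_terms(ontology)
    sig_names = sorted({s for ss in hits.values() for s in ss})
    links: dict[str, set] = {}
    for leaf in leaves:
        chosen = rng.choice(len(sig_names), size=min(config.sigs_per_term, len(sig_names)),
                            replace=False)
        links[leaf] = {sig_names[int(c)] for c in chosen}
    base_logit = float(np.log(config.label_density / (1 - config.label_density)))
    effect = config.feature_signal * FEATURE_EFFECT_SCALE
    base: dict[str, set] = {}
    for p in proteins:
        mine = hits[p]
        terms = set()
        for leaf in leaves:
            logit = base_logit + effect * len(links[leaf] & mine)
            if rng.random() < 1.0 / (1.0 + np.exp(-logit)):
                terms.add(leaf)
        if not terms:
            terms.add(leaves[int(rng.integers(len(leaves)))])
        base[p] = terms
    return base, links


def generate_network(config: SynthConfig, base_terms: dict, species: dict,
                     rng: np.random.Generator | None = None,
                     nodes: list | None = None) -> ProteinGraph:
    """Within-species random graph whose edge probability rises with the number
    of shared latent terms (homophily β) and whose weights increase with it."""
    rng = rng or np.random.default_rng(config.seed + 1)
    nodes = nodes if nodes is not None else sorted(base_terms)
    by_species: dict[str, list] = {}
    for p in nodes:
        by_species.setdefault(species[p], []).append(p)
    edges = []
    for members in by_species.values():
        ns = len(members)
        if ns < 2:
            continue
        p0 = min(1.0, config.mean_degree / (ns - 1))
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                shared = len(base_terms[u] & base_terms[v])
                p_edge = min(1.0, p0 * (1.0 + 5.0 * config.homophily * shared))
                if rng.random() < p_edge:
                    w = min(1.0, 0.3 + 0.15 * shared + float(rng.uniform(0, 0.15)))
                    edges.append((u, v, w))
    return ProteinGraph(nodes, edges)


def generate_annotations(config: SynthConfig, ontology: Ontology, base_terms: dict,
                         graph: ProteinGraph, rng: np.random.Generator | None = None,
                         role: dict | None = None):
    """Copy neighbor terms (probability s_n per term of one random neighbor),
    assign time stamps so a held-out fraction becomes no-knowledge test
    proteins, and build the benchmark split."""
    rng = rng or np.random.default_rng(config.seed + 2)
    proteins = sorted(base_terms)
    neighbors = {p: sorted(n for n, _ in graph.neighbors(p)) if p in graph else []
                 for p in proteins}
    final: dict[str, set] = {}
    for p in proteins:
        terms = set(base_terms[p])
        if neighbors[p] and config.network_signal > 0:
            nbr = neighbors[p][int(rng.integers(len(neighbors[p])))]
            for t in sorted(base_terms[nbr]):
                if rng.random() < config.network_signal:
                    terms.add(t)
        final[p] = terms

    if role is None:
        n = len(proteins)
        order = rng.permutation(n)
        n_test = int(round(config.test_fraction * n))
        n_valid = int(round(config.valid_fraction * n))
        role = {}
        for rank, idx in enumerate(order):
            p = proteins[int(idx)]
            role[p] = ("test" if rank < n_test
                       else "valid" if rank < n_test + n_valid else "train")
    date_of = {"train": TRAIN_DATE, "valid": VALID_DATE, "test": TEST_DATE}
    records = []
    for p in proteins:
        d = date_of[role[p]]
        for t in sorted(final[p]):
            ev = _EVIDENCE_POOL[int(rng.integers(len(_EVIDENCE_POOL)))]
            records.append(AnnotationRecord(p, t, ev, d))
    split = make_time_split(records, ontology, config.domain, T0, T1,
                            valid_window=VALID_WINDOW)
    return records, split, role


def generate_benchmark(config: SynthConfig | None = None) -> SynthBenchmark:
    """End-to-end generation; deterministic in ``config.seed``."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    ontology = generate_dag(config.n_terms, config.dag_depth, config.seed, config.domain)
    signatures, hits, homology, species = generate_proteins(config, rng)
    proteins = signatures.proteins
    base_terms, _links = _assign_base_terms(config, ontology, hits, proteins, rng)

    # hold some test proteins out of the network to exercise homology fallback
    order = rng.permutation(len(proteins))
    n_test = int(round(config.test_fraction * len(proteins)))
    test_pool = [proteins[int(i)] for i in order[:n_test]]
    n_off = int(round(config.offnet_fraction * n_test))
    off_network = set(test_pool[:n_off])
    nodes = [p for p in proteins if p not in off_network]
    graph = generate_network(config, base_terms, species, rng, nodes=nodes)

    # role assignment reuses `order` so off-network proteins are test proteins
    n_valid = int(round(config.valid_fraction * len(proteins)))
    role = {}
    for rank, idx in enumerate(order):
        p = proteins[int(idx)]
        role[p] = "test" if rank < n_test else "valid" if rank < n_test + n_valid else "train"
    records, split, role = generate_annotations(config, ontology, base_terms, graph,
                                                rng, role=role)
    return SynthBenchmark(ontology=ontology, hits=hits, signatures=signatures,
                          graph=graph, homology=homology, records=records,
                          split=split, species=species, base_terms=base_terms,
                          config=config)


# ------------------------------------------------------------------ writers


_NAMESPACE = {"MFO": "molecular_function", "BPO": "biological_process",
              "CCO": "cellular_component"}


def write_obo(ontology: Ontology, stream):
    stream.write("format-version: 1.2\nontology: go-synthetic\n")
    for term in sorted(ontology.terms):
        stream.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
        stream.write(f"namespace: {_NAMESPACE[ontology.domain[term]]}\n")
        for p in sorted(ontology.parents[term]):
            stream.write(f"is_a: {p} ! synthetic term {p}\n")


def write_interproscan_tsv(hits: dict, stream):
    """Emit minimal InterProScan-tabular lines (member accession in column 5,
    InterPro entry accession in column 12)."""
    for p in sorted(hits):
        accs = sorted(hits[p])
        if not accs:
            stream.write("\t".join([p, "-", "0", "SYN", "-", "-", "0", "0",
                                    "-", "T", "2020-01-01", "-", "-"]) + "\n")
        for acc in accs:
            stream.write("\t".join([p, "-", "100", "SYN", f"S{acc}",
                                    "synthetic signature", "1", "100", "1e-10",
                                    "T", "2020-01-01", acc, "synthetic entry"]) + "\n")


def write_benchmark(bench: SynthBenchmark, outdir) -> dict:
    """Write the full fixture directory; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": outdir / "ontology.obo",
        "interproscan": outdir / "interproscan.tsv",
        "network": outdir / "network.tsv",
        "homology": outdir / "homology.tsv",
        "annotations": outdir / "annotations.tsv",
        "provenance": outdir / "provenance.json",
    }
    with open(paths["ontology"], "w") as f:
        write_obo(bench.ontology, f)
    with open(paths["interproscan"], "w") as f:
        write_interproscan_tsv(bench.hits, f)
    with open(paths["network"], "w") as f:
        write_string_edges(bench.graph, f)
    with open(paths["homology"], "w") as f:
        write_homology_tsv(bench.homology, f)
    with open(paths["annotations"], "w") as f:
        write_annotation_tsv(bench.records, f)
    with open(paths["provenance"], "w") as f:
        json.dump(bench.provenance, f, indent=2)
    return {k: str(v) for k, v in paths.items()}
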