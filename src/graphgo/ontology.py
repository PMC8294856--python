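"""Gene Ontology handling: OBO parsing, evidence filtering, true-path propagation
and time-stamped no-knowledge benchmark splits.

The Gene Ontology (GO) is a directed acyclic graph of terms in three domains
(MFO: molecular function, BPO: biological process, CCO: cellular component).
A protein annotated with a term is implicitly annotated with every ancestor of
that term (the true-path rule), so annotation matrices here are always closed
under ancestors within a domain.

Benchmark construction follows the CAFA protocol: training proteins are those
with an accepted experimental annotation before a cutoff date t0; test proteins
are *no-knowledge* proteins — no accepted annotation in ANY domain before t0,
and at least one in the target domain inside [t0, t1).
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
from scipy import sparse

logger = logging.getLogger(__name__)

#: GO domain labels used throughout the package.
DOMAINS = ("MFO", "BPO", "CCO")

#: OBO namespace tag -> domain label.
NAMESPACE_TO_DOMAIN = {
    "molecular_function": "MFO",
    "biological_process": "BPO",
    "cellular_component": "CCO",
}

#: Default accepted experimental evidence codes. 'TA' is accepted as an alias
#: of 'TAS' (traceable author statement), which is the GOA spelling.
EXPERIMENTAL_EVIDENCE = frozenset(
    {"IDA", "IPI", "EXP", "IGI", "IMP", "IEP", "IC", "TAS", "TA"}
)

#: Ontology relationships that carry the true-path rule.
PROPAGATING_RELATIONSHIPS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, dangling parents)."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein–GO-term assignment with its evidence code and date."""

    protein: str
    term: str
    evidence: str
    date: _dt.date

    def __post_init__(self):
        if not isinstance(self.date, _dt.date):
            object.__setattr__(self, "date", _dt.date.fromisoformat(str(self.date)))


class Ontology:
    """A parsed GO DAG restricted to is_a / part_of relationships.

    Parameters
    ----------
    parents
        Map term -> set of direct parents (within the same domain).
    domain
        Map term -> one of ``MFO``/``BPO``/``CCO``.
    """

    def __init__(self, parents: Mapping[str, set], domain: Mapping[str, str]):
        self.parents = {t: frozenset(p) for t, p in parents.items()}
        self.domain = dict(domain)
        self.terms = set(self.parents)
        self._validate()
        self.roots = {
            self.domain[t]: t for t in self.terms if not self.parents[t]
        }
        self._ancestor_cache: dict[str, frozenset] = {}

    def _validate(self):
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise OntologyError(f"term {t} references unknown parent {p}")
        g = nx.DiGraph(
            (t, p) for t, ps in self.parents.items() for p in ps
        )
        if g.number_of_nodes() and not nx.is_directed_acyclic_graph(g):
            edge = nx.find_cycle(g)[0]
            raise OntologyError(f"cycle detected through edge {edge[0]} -> {edge[1]}")
        for dom in set(self.domain.values()):
            roots = [
                t for t in self.terms if self.domain[t] == dom and not self.parents[t]
            ]
            if len(roots) != 1:
                raise OntologyError(f"domain {dom} has {len(roots)} roots, expected 1")

    def ancestors(self, term: str) -> frozenset:
        """All ancestors of ``term`` (excluding the term itself)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out = set()
        stack = list(self.parents[term])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents[p])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def terms_in_domain(self, domain: str) -> set:
        return {t for t in self.terms if self.domain[t] == domain}

    def root(self, domain: str) -> str:
        return self.roots[domain]


def load_obo(stream) -> Ontology:
    """Parse OBO 1.2 text into an :class:`Ontology`.

    Obsolete terms are dropped, relationships other than is_a/part_of are
    ignored, and parent links crossing GO domains are severed. A cycle or a
    reference to an unknown parent is a hard error.
    """
    graph = obonet.read_obo(stream, ignore_obsolete=True)
    domain = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns in NAMESPACE_TO_DOMAIN:
            domain[node] = NAMESPACE_TO_DOMAIN[ns]
    parents: dict[str, set] = {t: set() for t in domain}
    for child, parent, key in graph.edges(keys=True):
        if key not in PROPAGATING_RELATIONSHIPS:
            continue
        if child not in domain:
            continue
        if parent not in domain:
            raise OntologyError(f"term {child} references unknown parent {parent}")
        if domain[parent] != domain[child]:
            continue  # cross-domain link severed
        parents[child].add(parent)
    return Ontology(parents, domain)


def filter_evidence(
    records: Sequence[AnnotationRecord],
    accepted: Iterable[str] = EXPERIMENTAL_EVIDENCE,
) -> list[AnnotationRecord]:
    """Keep records whose evidence code is in ``accepted`` (order preserved)."""
    accepted = set(accepted)
    if not accepted:
        raise ValueError("accepted evidence-code set must be non-empty")
    if "TAS" in accepted:
        accepted.add("TA")
    if "TA" in accepted:
        accepted.add("TAS")
    return [r for r in records if r.evidence in accepted]


class AnnotationTable:
    """Binary protein x GO-term annotation matrix for one GO domain.

    The matrix is closed under ancestor propagation; the domain root is
    excluded from the scored columns by default (CAFA convention — predicting
    the root carries no information).
    """

    def __init__(self, proteins: Sequence[str], terms: Sequence[str], matrix):
        self.proteins = list(proteins)
        self.terms = list(terms)
        self.matrix = sparse.csr_matrix(matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.proteins), len(self.terms)):
            raise ValueError("matrix shape does not match protein/term axes")
        self._protein_index = {p: i for i, p in enumerate(self.proteins)}
        self._term_index = {t: j for j, t in enumerate(self.terms)}

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def protein_row(self, protein: str) -> set:
        """The set of terms annotated to ``protein``."""
        i = self._protein_index[protein]
        row = self.matrix.getrow(i)
        return {self.terms[j] for j in row.indices}

    def term_counts(self) -> np.ndarray:
        """Number of annotated proteins per term (column sums)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def restrict_terms(self, terms: Sequence[str]) -> "AnnotationTable":
        """Project onto the given term columns (missing terms become zeros)."""
        cols = []
        n = len(self.proteins)
        for t in terms:
            j = self._term_index.get(t)
            if j is None:
                cols.append(sparse.csr_matrix((n, 1), dtype=np.int8))
            else:
                cols.append(self.matrix[:, j])
        matrix = sparse.hstack(cols, format="csr") if cols else sparse.csr_matrix((n, 0))
        return AnnotationTable(self.proteins, terms, matrix)


def propagate_true_path(
    records: Sequence[AnnotationRecord],
    ontology: Ontology,
    domain: str,
    proteins: Sequence[str] | None = None,
    include_root: bool = False,
) -> AnnotationTable:
    """Propagate annotations up the DAG (true-path rule) within one domain.

    Records whose term belongs to another domain are skipped (a warning with
    the skip count is emitted). Proteins default to first-appearance order of
    the surviving records; term columns are sorted for reproducibility.
    """
    root = ontology.root(domain)
    skipped = 0
    per_protein: dict[str, set] = {}
    if proteins is not None:
        per_protein = {p: set() for p in proteins}
    for r in records:
        if r.term not in ontology.terms or ontology.domain[r.term] != domain:
            skipped += 1
            continue
        closure = {r.term} | set(ontology.ancestors(r.term))
        per_protein.setdefault(r.protein, set()).update(closure)
    if skipped:
        warnings.warn(f"skipped {skipped} records outside domain {domain}")
    term_set = set()
    for s in per_protein.values():
        term_set |= s
    if not include_root:
        term_set.discard(root)
        for s in per_protein.values():
            s.discard(root)
    protein_order = list(per_protein)
    terms = sorted(term_set)
    term_index = {t: j for j, t in enumerate(terms)}
    rows, cols = [], []
    for i, p in enumerate(protein_order):
        for t in per_protein[p]:
            rows.append(i)
            cols.append(term_index[t])
    matrix = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(protein_order), len(terms)),
    )
    return AnnotationTable(protein_order, terms, matrix)


@dataclass
class BenchmarkSplit:
    """Time-stamped train/valid/test split over one GO domain."""

    train: AnnotationTable
    valid: AnnotationTable | None
    test: AnnotationTable
    t0: _dt.date
    t1: _dt.date
    domain: str = ""


def _as_date(d) -> _dt.date:
    return d if isinstance(d, _dt.date) else _dt.date.fromisoformat(str(d))


def make_time_split(
    records: Sequence[AnnotationRecord],
    ontology: Ontology,
    domain: str,
    t0,
    t1,
    valid_window: tuple | None = None,
    accepted: Iterable[str] = EXPERIMENTAL_EVIDENCE,
) -> BenchmarkSplit:
    """Build a CAFA-style benchmark split from dated annotation records.

    Train: proteins with >=1 accepted annotation in ``domain`` dated before the
    training cutoff (the start of ``valid_window`` when given, else ``t0``),
    annotated with those records only. Test: no-knowledge proteins — zero
    accepted annotations in ANY domain before ``t0``, and >=1 in ``domain``
    within ``[t0, t1)``. The validation set is built identically over
    ``valid_window`` (no-knowledge relative to its own start). Dates compare at
    day granularity with half-open windows.
    """
    t0, t1 = _as_date(t0), _as_date(t1)
    if not t0 < t1:
        raise ValueError("t0 must precede t1")
    records = filter_evidence(records, accepted)
    in_domain = [
        r
        for r in records
        if r.term in ontology.terms and ontology.domain[r.term] == domain
    ]
    train_cutoff = _as_date(valid_window[0]) if valid_window else t0

    first_any: dict[str, _dt.date] = {}
    for r in records:
        if r.protein not in first_any or r.date < first_any[r.protein]:
            first_any[r.protein] = r.date

    def window_table(lo: _dt.date, hi: _dt.date) -> AnnotationTable:
        subset = [r for r in in_domain if lo <= r.date < hi]
        no_knowledge = [r for r in subset if first_any[r.protein] >= lo]
        return propagate_true_path(no_knowledge, ontology, domain)

    train_records = [r for r in in_domain if r.date < train_cutoff]
    train = propagate_true_path(train_records, ontology, domain)
    test = window_table(t0, t1)
    if train.n_proteins == 0:
        raise ValueError(f"empty training set before {train_cutoff}")
    if test.n_proteins == 0:
        raise ValueError(f"empty test set in [{t0}, {t1})")
    valid = None
    if valid_window is not None:
        v0, v1 = _as_date(valid_window[0]), _as_date(valid_window[1])
        valid = window_table(v0, v1)
    return BenchmarkSplit(train=train, valid=valid, test=test, t0=t0, t1=t1, domain=domain)


def select_scored_terms(table: AnnotationTable, min_train_count: int = 0) -> AnnotationTable:
    """Restrict columns to terms with at least ``min_train_count`` annotated
    proteins; column order is preserved."""
    if min_train_count < 0:
        raise ValueError("min_train_count must be >= 0")
    counts = table.term_counts()
    keep = [t for t, c in zip(table.terms, counts) if c >= min_train_count]
    return table.restrict_terms(keep)


def read_annotation_tsv(stream) -> list[AnnotationRecord]:
    """Read the package's annotation TSV: protein, GO term, evidence, ISO date."""
    out = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        protein, term, evidence, date = line.split("\t")[:4]
        out.append(AnnotationRecord(protein, term, evidence, _dt.date.fromisoformat(date)))
    return out


def read_gaf(stream) -> list[AnnotationRecord]:
    """Read GAF 2.x: columns 2 (protein), 5 (GO id), 7 (evidence), 14 (date)."""
    out = []
    for line in stream:
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 14:
            continue
        date = _dt.datetime.strptime(cols[13], "%Y%m%d").date()
        out.append(AnnotationRecord(cols[1], cols[4], cols[6], date))
    return out


def write_annotation_tsv(records: Sequence[AnnotationRecord], stream):
    for r in records:
        stream.write(f"{r.protein}\t{r.term}\t{r.evidence}\t{r.date.isoformat()}\n")
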