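"""InterPro signature features.

Each protein is represented by a binary vector x_i in {0,1}^m marking which
InterPro signatures (family/domain/motif entries) were found on it by
InterProScan. The vocabulary of m signatures is frozen when the feature space
is built; signatures first seen at prediction time are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

# InterProScan tabular columns (0-based): 0 protein accession,
# 4 member-database signature accession, 11 InterPro entry accession.
_COL_PROTEIN = 0
_COL_MEMBER = 4
_COL_INTERPRO = 11


@dataclass(frozen=True)
class SignatureVocabulary:
    """Frozen, lexicographically ordered signature accession list."""

    signatures: tuple

    def __post_init__(self):
        if len(set(self.signatures)) != len(self.signatures):
            raise ValueError("duplicate signature accessions in vocabulary")
        if not self.signatures:
            raise ValueError("vocabulary must contain at least one signature")

    @property
    def index(self) -> dict:
        return {s: j for j, s in enumerate(self.signatures)}

    def __len__(self) -> int:
        return len(self.signatures)


class SignatureMatrix:
    """N x m sparse binary feature matrix over a frozen vocabulary."""

    def __init__(self, proteins: Sequence[str], vocabulary: SignatureVocabulary, matrix):
        self.proteins = list(proteins)
        self.vocabulary = vocabulary
        self.matrix = sparse.csr_matrix(matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.proteins), len(vocabulary)):
            raise ValueError("matrix shape does not match proteins/vocabulary")
        self._protein_index = {p: i for i, p in enumerate(self.proteins)}

    @property
    def m(self) -> int:
        return len(self.vocabulary)

    def rows(self, proteins: Sequence[str]) -> sparse.csr_matrix:
        idx = [self._protein_index[p] for p in proteins]
        return self.matrix[idx]

    def __contains__(self, protein: str) -> bool:
        return protein in self._protein_index


def read_interproscan_tsv(stream, use_interpro_accession: bool = True) -> dict:
    """Parse InterProScan tabular output into protein -> set of accessions.

    By default the InterPro entry accession (column 12) defines signature
    identity; set ``use_interpro_accession=False`` to use the member-database
    signature (column 5) instead. '-' and empty accessions contribute nothing.
    Malformed lines are skipped with a logged count; if every line is
    malformed, that is a hard error.
    """
    col = _COL_INTERPRO if use_interpro_accession else _COL_MEMBER
    hits: dict[str, set] = {}
    n_lines = n_bad = 0
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        n_lines += 1
        cols = line.split("\t")
        if len(cols) <= col or not cols[_COL_PROTEIN]:
            n_bad += 1
            continue
        acc = cols[col].strip()
        hits.setdefault(cols[_COL_PROTEIN], set())
        if acc and acc != "-":
            hits[cols[_COL_PROTEIN]].add(acc)
    if n_bad:
        logger.warning("skipped %d malformed InterProScan lines", n_bad)
    if n_lines and n_bad == n_lines:
        raise ValueError("all InterProScan lines were malformed")
    return hits


def build_vocabulary(hits: Mapping[str, Iterable[str]], proteins: Sequence[str]) -> SignatureVocabulary:
    """Vocabulary of signatures hitting at least one listed protein, in
    lexicographic column order."""
    if not proteins:
        raise ValueError("protein list must be non-empty")
    seen = set()
    for p in proteins:
        seen.update(hits.get(p, ()))
    if not seen:
        raise ValueError("no signatures hit any listed protein (m = 0)")
    return SignatureVocabulary(tuple(sorted(seen)))


def vectorize(
    hits: Mapping[str, Iterable[str]],
    vocabulary: SignatureVocabulary,
    proteins: Sequence[str],
) -> SignatureMatrix:
    """Binary matrix of in-vocabulary hits; out-of-vocabulary accessions are
    silently dropped and all-zero rows are permitted."""
    index = vocabulary.index
    rows, cols = [], []
    for i, p in enumerate(proteins):
        for acc in hits.get(p, ()):
            j = index.get(acc)
            if j is not None:
                rows.append(i)
                cols.append(j)
    matrix = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(proteins), len(vocabulary)),
    )
    matrix.data[:] = 1.0  # collapse duplicates to binary
    return SignatureMatrix(proteins, vocabulary, matrix)


def save_signature_matrix(sm: SignatureMatrix, stream):
    """Serialize as a JSON header line followed by COO triplets."""
    header = {"proteins": sm.proteins, "signatures": list(sm.vocabulary.signatures)}
    stream.write(json.dumps(header) + "\n")
    coo = sm.matrix.tocoo()
    for i, j in zip(coo.row, coo.col):
        stream.write(f"{i}\t{j}\n")


def load_signature_matrix(stream) -> SignatureMatrix:
    header = json.loads(stream.readline())
    vocab = SignatureVocabulary(tuple(header["signatures"]))
    rows, cols = [], []
    for line in stream:
        if not line.strip():
            continue
        i, j = line.split("\t")
        rows.append(int(i))
        cols.append(int(j))
    matrix = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(header["proteins"]), len(vocab)),
    )
    return SignatureMatrix(header["proteins"], vocab, matrix)
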