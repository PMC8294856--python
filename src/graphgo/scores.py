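"""Prediction score matrices and the CAFA prediction TSV format."""

from __future__ import annotations

from typing import Sequence

import numpy as np


class ScoreMatrix:
    """Per-protein, per-term prediction scores in [0, 1].

    ``strata`` optionally maps each protein to its coverage stratum:
    ``STRI`` (in the network), ``HOMO`` (off-network with an in-network
    homolog) or ``NONE`` (neither; such rows are all-zero by construction).
    """

    def __init__(self, proteins: Sequence[str], terms: Sequence[str], values, strata: dict | None = None):
        self.proteins = list(proteins)
        self.terms = list(terms)
        self.values = np.asarray(values, dtype=np.float64)
        if self.values.shape != (len(self.proteins), len(self.terms)):
            raise ValueError("score matrix shape does not match axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
        self.strata = dict(strata) if strata else {}
        self._protein_index = {p: i for i, p in enumerate(self.proteins)}
        self._term_index = {t: j for j, t in enumerate(self.terms)}

    def row(self, protein: str) -> np.ndarray:
        return self.values[self._protein_index[protein]]

    def predicted_terms(self, protein: str, threshold: float) -> set:
        r = self.row(protein)
        return {self.terms[j] for j in np.flatnonzero(r >= threshold)}

    def restrict(self, proteins: Sequence[str], terms: Sequence[str]) -> "ScoreMatrix":
        """Align to the given axes; missing proteins/terms score zero."""
        out = np.zeros((len(proteins), len(terms)))
        col = [self._term_index.get(t, -1) for t in terms]
        for i, p in enumerate(proteins):
            ri = self._protein_index.get(p)
            if ri is None:
                continue
            for j, c in enumerate(col):
                if c >= 0:
                    out[i, j] = self.values[ri, c]
        strata = {p: self.strata[p] for p in proteins if p in self.strata}
        return ScoreMatrix(proteins, terms, out, strata)


def write_cafa_tsv(sm: ScoreMatrix, stream, round_2dp: bool = False, min_score: float = 0.0):
    """Write (protein, GO term, score) lines, optionally with CAFA 2-decimal
    rounding; zero-score pairs are omitted unless ``min_score`` is negative."""
    for i, p in enumerate(sm.proteins):
        for j, t in enumerate(sm.terms):
            s = sm.values[i, j]
            if round_2dp:
                s = round(s, 2)
            if s > min_score:
                stream.write(f"{p}\t{t}\t{s:.6f}\n" if not round_2dp else f"{p}\t{t}\t{s:.2f}\n")


def read_cafa_tsv(stream, proteins: Sequence[str] | None = None, terms: Sequence[str] | None = None) -> ScoreMatrix:
    triples = []
    for line in stream:
        line = line.strip()
        if not line or line.startswith(("#", "AUTHOR", "MODEL", "KEYWORDS", "END")):
            continue
        p, t, s = line.split("\t")[:3]
        triples.append((p, t, float(s)))
    if proteins is None:
        seen = []
        known = set()
        for p, _, _ in triples:
            if p not in known:
                known.add(p)
                seen.append(p)
        proteins = seen
    if terms is None:
        terms = sorted({t for _, t, _ in triples})
    values = np.zeros((len(proteins), len(terms)))
    pi = {p: i for i, p in enumerate(proteins)}
    ti = {t: j for j, t in enumerate(terms)}
    for p, t, s in triples:
        if p in pi and t in ti:
            values[pi[p], ti[t]] = s
    return ScoreMatrix(proteins, terms, values)
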