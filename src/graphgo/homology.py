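"""Precomputed pairwise sequence-homology table (BLAST/DIAMOND outfmt-6 style).

Bit-scores weight the homology k-NN baseline and pick the nearest in-network
homolog for proteins absent from the protein network; percent identity drives
the *difficult*-protein stratification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class HomologyHit:
    bit_score: float
    evalue: float = 0.0
    identity: float = 100.0

    def __post_init__(self):
        if self.bit_score <= 0:
            raise ValueError("bit-scores must be positive")


class HomologyTable:
    """Map (query, subject) -> :class:`HomologyHit`. Storage is directional;
    symmetric pairs may be present or not depending on the search."""

    def __init__(self):
        self._pairs: dict[tuple, HomologyHit] = {}
        self._by_query: dict[str, dict] = {}

    def add(self, query: str, subject: str, bit_score: float, evalue: float = 0.0, identity: float = 100.0):
        if query == subject:
            return  # self-hits carry no transfer information
        hit = HomologyHit(bit_score, evalue, identity)
        old = self._pairs.get((query, subject))
        if old is None or hit.bit_score > old.bit_score:
            self._pairs[(query, subject)] = hit
            self._by_query.setdefault(query, {})[subject] = hit

    def hits(self, query: str, candidates: Iterable[str] | None = None, e_cutoff: float | None = None) -> dict:
        """Subjects hit by ``query`` (optionally restricted and e-value filtered)."""
        out = self._by_query.get(query, {})
        if candidates is not None:
            cand = set(candidates)
            out = {s: h for s, h in out.items() if s in cand}
        if e_cutoff is not None:
            out = {s: h for s, h in out.items() if h.evalue <= e_cutoff}
        return dict(out)

    def best_homolog(self, query: str, candidates: Iterable[str] | None = None):
        """Highest-bit-score subject (ties broken lexicographically), or None."""
        hits = self.hits(query, candidates)
        if not hits:
            return None
        return min(hits, key=lambda s: (-hits[s].bit_score, s))

    def max_identity(self, query: str, candidates: Iterable[str] | None = None) -> float | None:
        hits = self.hits(query, candidates)
        if not hits:
            return None
        return max(h.identity for h in hits.values())

    def __len__(self) -> int:
        return len(self._pairs)


def read_homology_tsv(stream) -> HomologyTable:
    """Read query, subject, bit-score[, e-value[, identity]] TSV lines."""
    table = HomologyTable()
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        q, s, bit = cols[0], cols[1], float(cols[2])
        ev = float(cols[3]) if len(cols) > 3 else 0.0
        ident = float(cols[4]) if len(cols) > 4 else 100.0
        if q != s:
            table.add(q, s, bit, ev, ident)
    return table


def write_homology_tsv(table: HomologyTable, stream):
    for (q, s), h in sorted(table._pairs.items()):
        stream.write(f"{q}\t{s}\t{h.bit_score:.2f}\t{h.evalue:.3g}\t{h.identity:.1f}\n")
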