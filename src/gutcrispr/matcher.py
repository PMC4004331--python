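"""Exhaustive full-length Hamming matching of short queries against a
contig corpus.

The matcher is exact (equivalent to a naive sliding-window scan) but uses
pigeonhole seeding for speed: a window within ``m`` mismatches of a query
must contain at least one of ``m + 1`` query chunks exactly, so exact
substring search for the chunks enumerates every candidate window, which
is then verified by a vectorised mismatch count.  N never matches, on
either side; the pigeonhole argument survives this convention because a
chunk with any N can never be mismatch-free.
"""

from __future__ import annotations

import numpy as np

from ._seq import encode, mismatch_profile, revcomp
from .types import Contig

_PAD = 100          # inter-contig separator length; must exceed any query
_SEP_CHAR = "X"     # never matches A/C/G/T/N
_SEP_CODE = 5


class TargetCorpus:
    """All target contigs concatenated for repeated query matching."""

    def __init__(self, contigs: dict[str, Contig]):
        self.ids: list[str] = list(contigs)
        sep = _SEP_CHAR * _PAD
        parts, starts, pos = [], [], 0
        for cid in self.ids:
            starts.append(pos)
            seq = contigs[cid].sequence
            parts.append(seq)
            parts.append(sep)
            pos += len(seq) + _PAD
        self.text = "".join(parts)
        self.codes = np.full(len(self.text), _SEP_CODE, dtype=np.uint8)
        self.starts = np.array(starts, dtype=np.int64)
        self.lengths = np.array([contigs[c].length for c in self.ids], dtype=np.int64)
        for cid, start in zip(self.ids, self.starts):
            seq = contigs[cid].sequence
            self.codes[start : start + len(seq)] = encode(seq)

    def _candidates(self, query: str, n_chunks: int) -> np.ndarray:
        """Window start positions (in corpus coordinates) to verify."""
        L = len(query)
        bounds = np.linspace(0, L, n_chunks + 1).astype(int)
        cands: set[int] = set()
        for a, b in zip(bounds, bounds[1:]):
            chunk = query[a:b]
            if "N" in chunk:
                continue        # an N chunk can never be mismatch-free
            here = self.text.find(chunk)
            while here != -1:
                start = here - a
                if start >= 0:
                    cands.add(start)
                here = self.text.find(chunk, here + 1)
        return np.fromiter(cands, dtype=np.int64, count=len(cands))

    def find(self, query: str, max_mismatches: int,
             *, both_strands: bool = True) -> list[tuple[str, int, str, int]]:
        """All (contig_id, position, strand, mismatches) full-length matches.

        Position is on the contig plus strand; a minus-strand entry means
        the reverse complement of the query matches there.
        """
        L = len(query)
        if L == 0 or L > _PAD:
            raise ValueError(f"query length {L} outside supported range 1..{_PAD}")
        out = []
        strands = (("+", query), ("-", revcomp(query))) if both_strands else (("+", query),)
        for strand, q in strands:
            cands = self._candidates(q, max_mismatches + 1)
            if cands.size == 0:
                continue
            cands = cands[cands + L <= len(self.codes)]
            windows = self.codes[cands[:, None] + np.arange(L)]
            mm = mismatch_profile(windows, encode(q))
            ok = mm <= max_mismatches
            for pos, m in zip(cands[ok], mm[ok]):
                idx = int(np.searchsorted(self.starts, pos, side="right")) - 1
                offset = int(pos - self.starts[idx])
                if offset + L <= int(self.lengths[idx]):
                    out.append((self.ids[idx], offset, strand, int(m)))
        out.sort()
        return out

    def matched_contigs(self, query: str, max_mismatches: int) -> set[str]:
        """Contigs containing at least one full-length match of the query."""
        return {cid for cid, _, _, _ in self.find(query, max_mismatches)}
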