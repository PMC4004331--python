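"""Repeat consensus, clustering, cassette orientation and cas-type calls.

Clustering emulates nucleotide BLASTCLUST semantics: two consensus repeats
are linked when a word-seeded ungapped local alignment on either strand
reaches the identity threshold over a span covering the required fraction
of the longer sequence; clusters are the connected components (single
linkage).  Repeats are short (~24-48 nt) and near-equal length, so simple
+1/-2 ungapped scoring is adequate; an exhaustive dynamic-programming
oracle bounds the approximation in the test suite.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

from ._seq import revcomp
from .types import Cassette, CasTypeCall, GeneAnnotation, RepeatCluster

log = logging.getLogger(__name__)

DEFAULT_CLUSTER_PARAMS = (0.50, 0.50, 15)   # min_identity, min_coverage, word_size
MATCH_SCORE, MISMATCH_SCORE = 1, -2

# signature cas genes -> system type (universal cas1/cas2 are uninformative)
DEFAULT_SIGNATURES = {"cas3": "I", "cas9": "II", "cas10": "III"}


def consensus_repeat(copies: list[str]) -> str:
    """Column-wise majority consensus over the modal-length repeat copies.

    Copies whose length differs from the modal length are ignored for
    voting (but still count toward the copy number reported elsewhere).
    Ties at a column go to the alphabetically first base.  If no length is
    shared by two copies, the first copy is returned verbatim.
    """
    if len(copies) < 2:
        raise ValueError("consensus needs >=2 repeat copies")
    by_len = Counter(len(c) for c in copies)
    best = max(by_len.values())
    if best < 2:
        log.warning("all %d repeat copies have distinct lengths; using first verbatim",
                    len(copies))
        return copies[0]
    # first length (in input order) achieving the modal count
    modal_len = next(len(c) for c in copies if by_len[len(c)] == best)
    group = [c for c in copies if len(c) == modal_len]
    out = []
    for col in zip(*group):
        counts = Counter(col)
        top = max(counts.values())
        out.append(min(b for b, n in counts.items() if n == top))
    return "".join(out)


@dataclass
class LinkAlignment:
    """Best word-seeded ungapped local alignment found between two repeats."""

    span: int
    matches: int
    strand: str      # strand of the second sequence

    @property
    def identity(self) -> float:
        return self.matches / self.span if self.span else 0.0


def _best_on_strand(a: str, bb: str, word_size: int, strand: str) -> LinkAlignment | None:
    """Best seeded ungapped alignment of a against one orientation of b.

    Every shared exact word seeds an extension to the maximal-scoring
    segment containing it (+1 match / -2 mismatch); among all seeded
    alignments the one with the largest matches, then span, is returned.
    Every seed is extended (repeats are short, so no diagonal dedup is
    needed for speed).
    """
    words: dict[str, list[int]] = defaultdict(list)
    for i in range(len(a) - word_size + 1):
        words[a[i : i + word_size]].append(i)

    best: LinkAlignment | None = None
    for j in range(len(bb) - word_size + 1):
        positions = words.get(bb[j : j + word_size])
        if not positions:
            continue
        for i in positions:
            # extend left of the seed
            left_gain = left_len = score = 0
            k = 1
            while i - k >= 0 and j - k >= 0:
                score += MATCH_SCORE if a[i - k] == bb[j - k] else MISMATCH_SCORE
                if score > left_gain:
                    left_gain, left_len = score, k
                k += 1
            # extend right of the seed
            right_gain = right_len = score = 0
            k = 0
            while i + word_size + k < len(a) and j + word_size + k < len(bb):
                score += (MATCH_SCORE if a[i + word_size + k] == bb[j + word_size + k]
                          else MISMATCH_SCORE)
                if score > right_gain:
                    right_gain, right_len = score, k + 1
                k += 1
            span = word_size + left_len + right_len
            matches = sum(
                1 for t in range(span)
                if a[i - left_len + t] == bb[j - left_len + t]
            )
            cand = LinkAlignment(span=span, matches=matches, strand=strand)
            if best is None or (cand.matches, cand.span) > (best.matches, best.span):
                best = cand
    return best


def _best_seeded_alignment(a: str, b: str, word_size: int) -> LinkAlignment | None:
    """Best seeded ungapped alignment of a vs b on either strand of b."""
    best = None
    for strand, bb in (("+", b), ("-", revcomp(b))):
        cand = _best_on_strand(a, bb, word_size, strand)
        if cand is not None and (
            best is None or (cand.matches, cand.span) > (best.matches, best.span)
        ):
            best = cand
    return best


def repeats_linked(
    a: str, b: str, params: tuple[float, float, int] = DEFAULT_CLUSTER_PARAMS
) -> bool:
    """BLASTCLUST-style link decision between two consensus repeats."""
    min_identity, min_coverage, word_size = params
    aln = _best_seeded_alignment(a, b, word_size)
    if aln is None:
        return False
    return (
        aln.identity >= min_identity
        and aln.span >= min_coverage * max(len(a), len(b))
    )


def best_relative_strand(a: str, b: str, word_size: int = 15) -> str:
    """Strand of b whose seeded alignment with a scores best: '+', '-' or '?'."""
    fwd = _best_on_strand(a, b, word_size, "+")
    rev = _best_on_strand(a, revcomp(b), word_size, "-")
    fwd_m = fwd.matches if fwd else 0
    rev_m = rev.matches if rev else 0
    if fwd_m == rev_m:
        return "?"
    return "+" if fwd_m > rev_m else "-"


def cluster_repeats(
    consensi: dict[str, str],
    params: tuple[float, float, int] = DEFAULT_CLUSTER_PARAMS,
) -> list[RepeatCluster]:
    """Single-linkage clustering of consensus repeats (BLASTCLUST semantics).

    ``consensi`` maps cassette id -> consensus repeat.  The partition is
    independent of input order; cluster ids are assigned by the smallest
    member cassette id.
    """
    ids = sorted(consensi)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            # keep the lexicographically smaller id as the root
            if ry < rx:
                rx, ry = ry, rx
            parent[ry] = rx

    for idx, x in enumerate(ids):
        for y in ids[idx + 1 :]:
            if repeats_linked(consensi[x], consensi[y], params):
                union(x, y)

    members: dict[str, set[str]] = defaultdict(set)
    for i in ids:
        members[find(i)].add(i)
    clusters = []
    for k, root in enumerate(sorted(members), 1):
        clusters.append(RepeatCluster(
            id=f"RC{k:03d}",
            member_cassette_ids=frozenset(members[root]),
            params=params,
        ))
    return clusters


def _cas_leader_end(
    cassette: Cassette, genes: list[GeneAnnotation], window: int, strict: bool
) -> str:
    """Leader end implied by the nearest adjacent cas gene, or 'unknown'."""
    cs, ce = cassette.interval
    candidates = []
    for g in genes:
        if g.contig_id != cassette.contig_id:
            continue
        gs, ge = g.interval
        if ge <= cs:                 # gene left of the cassette
            gap, side, toward = cs - ge, "left", "+"
        elif gs >= ce:               # gene right of the cassette
            gap, side, toward = gs - ce, "right", "-"
        else:
            continue                 # overlapping: ambiguous, skip
        if gap > window:
            continue
        if strict and g.strand != toward:
            continue
        candidates.append((gap, side))
    if not candidates:
        return "unknown"
    candidates.sort()
    return candidates[0][1]


def orient_cassettes(
    cassettes: list[Cassette],
    cas_annotations: list[GeneAnnotation],
    clusters: list[RepeatCluster] | None = None,
    *,
    window: int = 2000,
    strict: bool = False,
) -> list[Cassette]:
    """Set leader ends and renumber spacer serials from the leader.

    Stage 1 orients cassettes by adjacent cas genes: the leader terminus is
    the cassette end nearest the cas locus (strict mode additionally
    requires the gene transcribed toward the cassette).  Stage 2 propagates
    orientation within repeat clusters assuming the repeat is encoded on
    the same strand for the whole cluster; conflicting evidence leaves a
    cassette unoriented.  Idempotent: a second pass changes nothing.
    """
    by_id = {c.id: c for c in cassettes}

    for cassette in cassettes:
        if cassette.leader_end == "unknown":
            end = _cas_leader_end(cassette, cas_annotations, window, strict)
            if end != "unknown":
                cassette.leader_end = end

    if clusters:
        for cluster in clusters:
            oriented = [by_id[i] for i in cluster.member_cassette_ids
                        if i in by_id and by_id[i].leader_end != "unknown"]
            pending = [by_id[i] for i in cluster.member_cassette_ids
                       if i in by_id and by_id[i].leader_end == "unknown"]
            if not oriented or not pending:
                continue
            for u in pending:
                implied = set()
                for m in oriented:
                    rel = best_relative_strand(m.repeat_consensus, u.repeat_consensus)
                    if rel == "?":
                        continue
                    same = rel == "+"
                    implied.add(m.leader_end if same
                                else ("left" if m.leader_end == "right" else "right"))
                if len(implied) == 1:
                    u.leader_end = implied.pop()
                elif len(implied) > 1:
                    log.info("cassette %s: conflicting cluster orientation evidence, "
                             "left unoriented", u.id)

    for cassette in cassettes:
        if cassette.leader_end == "unknown":
            continue
        n = cassette.n_spacers
        for idx, sp in enumerate(cassette.spacers, 1):   # coordinate order
            sp.serial = n + 1 - idx if cassette.leader_end == "right" else idx
            sp.provisional = False
    return cassettes


def assign_cas_type(
    cassette_id: str,
    genes: list[GeneAnnotation | str],
    signatures: dict[str, str] = DEFAULT_SIGNATURES,
) -> CasTypeCall:
    """Classify a cassette's CRISPR-cas system from its adjacent cas genes.

    cas1/cas2 are universal markers present across all types and do not
    differentiate; exactly one signature gene fixes the type, none or
    conflicting signatures leave the call unclassified.
    """
    names = sorted({g.name if isinstance(g, GeneAnnotation) else str(g).lower()
                    for g in genes})
    hits = [(n, signatures[n]) for n in names if n in signatures]
    types = sorted({t for _, t in hits})
    if len(types) == 1:
        return CasTypeCall(cassette_id=cassette_id, type=types[0],
                           evidence=tuple(n for n, _ in hits))
    return CasTypeCall(cassette_id=cassette_id, type="unclassified",
                       evidence=tuple(n for n, _ in hits) or tuple(names))
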