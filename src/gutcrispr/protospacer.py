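"""Protospacer discovery, the repeat-contamination filter, the pseudospacer
null model, and PAM scanning.

The default matcher is an exhaustive both-strand sliding-window Hamming
scan at full spacer length, which avoids the word-size edge artifacts of
seeded aligners on short queries (ingest + extension of external BLAST
tabular hits is kept for interoperability).  A hit is *reliable* when its
full-length mismatch count is within the threshold (default 4) and the
source cassette's repeat does not also match the target contig.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from ._seq import revcomp
from .io import BlastHit
from .matcher import TargetCorpus
from .types import Contig, Interval, ProtospacerHit, Spacer

log = logging.getLogger(__name__)

MAX_MISMATCHES = 4
FLANK_LEN = 10
CONTAMINATION_BUDGET_FRACTION = 0.15   # mismatch budget for repeat/flank scans


def contamination_budget(query_length: int) -> int:
    """Mismatch budget for repeat/flank contamination scans (~15% of length)."""
    return math.ceil(CONTAMINATION_BUDGET_FRACTION * query_length)


def _window_excluded(pos: int, window: int, intervals: list[Interval]) -> bool:
    """True when the window [pos, pos+window) overlaps any interval."""
    return any(pos < e and s < pos + window for s, e in intervals)


def _excluded_mask(length: int, window: int, intervals: list[Interval]) -> np.ndarray:
    """Boolean mask over window start positions whose window overlaps an interval."""
    n_pos = length - window + 1
    mask = np.zeros(max(n_pos, 0), dtype=bool)
    for s, e in intervals:
        lo = max(0, s - window + 1)
        hi = min(n_pos, e)
        if hi > lo:
            mask[lo:hi] = True
    return mask


def _flanks(target_seq: str, interval: Interval, strand: str) -> tuple[str, str]:
    """Up-to-10-nt flanks read 5'->3' on the hit strand."""
    s, e = interval
    left_plus = target_seq[max(0, s - FLANK_LEN) : s]
    right_plus = target_seq[e : e + FLANK_LEN]
    if strand == "+":
        return left_plus, right_plus
    return revcomp(right_plus), revcomp(left_plus)


def scan_targets(
    spacers: list[Spacer],
    contigs: dict[str, Contig],
    cassette_intervals: dict[str, list[Interval]],
    *,
    max_mismatches: int = MAX_MISMATCHES,
    individual_of_cassette: dict[str, str] | None = None,
    corpus: TargetCorpus | None = None,
) -> list[ProtospacerHit]:
    """Exhaustive both-strand full-length Hamming scan of spacers vs contigs.

    Windows overlapping any accepted-or-candidate cassette interval are
    excluded, which also excludes every spacer's own source locus.  N bases
    count as mismatches on either side.

    ``corpus`` may carry a prebuilt :class:`TargetCorpus` over the same
    contigs to avoid rebuilding it across calls.
    """
    corpus = corpus or TargetCorpus(contigs)
    hits: list[ProtospacerHit] = []
    for spacer in spacers:
        L = spacer.length
        ind = (individual_of_cassette or {}).get(spacer.cassette_id, "")
        for cid, pos, strand, mm in corpus.find(spacer.sequence, max_mismatches):
            if _window_excluded(pos, L, cassette_intervals.get(cid, [])):
                continue
            iv = (pos, pos + L)
            fl, fr = _flanks(contigs[cid].sequence, iv, strand)
            hits.append(ProtospacerHit(
                spacer=spacer,
                spacer_individual=ind,
                target_contig_id=cid,
                target_interval=iv,
                strand=strand,
                mismatches=mm,
                flank_left=fl,
                flank_right=fr,
                source="internal_scan",
            ))
    # dedupe by (spacer identity, target, interval, strand)
    seen: set[tuple] = set()
    unique = []
    for h in hits:
        key = (id(h.spacer), h.target_contig_id, h.target_interval, h.strand)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    return unique


def extend_blast_hit(
    raw: BlastHit,
    spacer: Spacer,
    target: Contig,
    *,
    max_mismatches: int = MAX_MISMATCHES,
    spacer_individual: str = "",
) -> ProtospacerHit | None:
    """Extend a raw BLAST hit to full spacer length and recount mismatches.

    Seeded aligners stop short of terminal mismatches on short queries, so
    the subject interval is widened to cover spacer positions 1..L before
    the ungapped mismatch count is taken.  Gapped raw hits are rejected
    (mismatches along the full spacer length is an ungapped notion), as are
    hits whose extension would run past a contig end.
    """
    if raw.gapped:
        log.info("gapped hit %s vs %s rejected", raw.query_id, raw.subject_id)
        return None
    L = spacer.length
    left_q = raw.query_start - 1          # spacer bases missing on the query left
    right_q = L - raw.query_end
    s0, e0 = raw.subject_interval
    if raw.strand == "+":
        s1, e1 = s0 - left_q, e0 + right_q
    else:
        s1, e1 = s0 - right_q, e0 + left_q
    if s1 < 0 or e1 > target.length:
        log.info("hit %s vs %s: full-length extension exceeds contig, rejected",
                 raw.query_id, raw.subject_id)
        return None
    window = target.sequence[s1:e1]
    aligned = window if raw.strand == "+" else revcomp(window)
    mm = sum(1 for a, b in zip(spacer.sequence, aligned) if a != b or a == "N")
    fl, fr = _flanks(target.sequence, (s1, e1), raw.strand)
    hit = ProtospacerHit(
        spacer=spacer,
        spacer_individual=spacer_individual,
        target_contig_id=target.id,
        target_interval=(s1, e1),
        strand=raw.strand,
        mismatches=mm,
        flank_left=fl,
        flank_right=fr,
        source="blast_extended",
    )
    return hit if mm <= max_mismatches else None


def repeat_contamination_filter(
    hits: list[ProtospacerHit],
    repeat_of_cassette: dict[str, str],
    contigs: dict[str, Contig],
    cassette_intervals: dict[str, list[Interval]] | None = None,
    *,
    corpus: TargetCorpus | None = None,
) -> list[ProtospacerHit]:
    """Flag hits whose source-cassette repeat also matches the hit's target.

    A spacer match inside an undetected cassette copy would look like a
    protospacer; if the repeat consensus of the spacer's cassette matches
    the same target contig (within ~15% mismatch budget, outside known
    cassette intervals), the hit fails the filter.  Returns the same hits
    with ``passed_repeat_filter`` set.
    """
    corpus = corpus or TargetCorpus(contigs)
    cache: dict[str, set[str]] = {}
    for h in hits:
        repeat = repeat_of_cassette.get(h.spacer.cassette_id, "")
        if not repeat:
            h.passed_repeat_filter = True
            continue
        if repeat not in cache:
            matched = set()
            for cid, pos, _strand, _mm in corpus.find(
                repeat, contamination_budget(len(repeat))
            ):
                if not _window_excluded(
                    pos, len(repeat), (cassette_intervals or {}).get(cid, [])
                ):
                    matched.add(cid)
            cache[repeat] = matched
        h.passed_repeat_filter = h.target_contig_id not in cache[repeat]
    return hits


def reliable_hits(hits: list[ProtospacerHit],
                  max_mismatches: int = MAX_MISMATCHES) -> list[ProtospacerHit]:
    return [h for h in hits if h.passed_repeat_filter and h.mismatches <= max_mismatches]


@dataclass
class Pseudospacer:
    """A random same-length stand-in for one spacer, with provenance."""

    original: Spacer
    contig_id: str
    interval: Interval
    sequence: str
    rule: str                 # same_contig | fallback_contig

    def as_spacer(self) -> Spacer:
        return Spacer(
            cassette_id=self.original.cassette_id,
            serial=self.original.serial,
            interval=self.interval,
            sequence=self.sequence,
            provisional=self.original.provisional,
        )


def make_pseudospacers(
    spacers: list[Spacer],
    contigs: dict[str, Contig],
    cassette_intervals: dict[str, list[Interval]],
    contig_of_cassette: dict[str, str],
    individual_of_contig: dict[str, str],
    seed: int,
) -> list[Pseudospacer]:
    """Replace each spacer by a random same-length fragment for the null model.

    The fragment comes from the spacer's own contig, drawn uniformly from
    positions fully outside cassette intervals; when both non-cassette
    flanks of the contig are shorter than 100 nt (cassette covering the
    contig almost completely), it is drawn instead from a random
    cassette-free contig of the same individual.
    """
    rng = np.random.default_rng(seed)
    out: list[Pseudospacer] = []
    cassette_free: dict[str, list[str]] = defaultdict(list)
    for cid, c in contigs.items():
        if not cassette_intervals.get(cid):
            cassette_free[c.individual_id].append(cid)

    def eligible_positions(cid: str, L: int) -> np.ndarray:
        codes_len = contigs[cid].length
        if codes_len < L:
            return np.empty(0, dtype=int)
        mask = _excluded_mask(codes_len, L, cassette_intervals.get(cid, []))
        return np.nonzero(~mask)[0]

    for spacer in spacers:
        L = spacer.length
        source = contig_of_cassette[spacer.cassette_id]
        ivs = cassette_intervals.get(source, [])
        left_flank = min(s for s, _ in ivs) if ivs else contigs[source].length
        right_flank = (contigs[source].length - max(e for _, e in ivs)) if ivs else 0
        use_fallback = left_flank < 100 and right_flank < 100
        pos = None
        chosen = source
        if not use_fallback:
            positions = eligible_positions(source, L)
            if positions.size:
                pos = int(positions[rng.integers(0, positions.size)])
        if pos is None:
            individual = individual_of_contig[source]
            pool = cassette_free.get(individual, [])
            pool = [c for c in pool if contigs[c].length >= L]
            if not pool:
                log.warning("no cassette-free contig for individual %s; "
                            "pseudospacer for %s:%d skipped",
                            individual, spacer.cassette_id, spacer.serial)
                continue
            chosen = pool[int(rng.integers(0, len(pool)))]
            pos = int(rng.integers(0, contigs[chosen].length - L + 1))
            rule = "fallback_contig"
        else:
            rule = "same_contig"
        out.append(Pseudospacer(
            original=spacer,
            contig_id=chosen,
            interval=(pos, pos + L),
            sequence=contigs[chosen].sequence[pos : pos + L],
            rule=rule,
        ))
    return out


def pseudo_flank_filter(
    pseudo_hits: list[ProtospacerHit],
    pseudospacers: list[Pseudospacer],
    repeat_of_cassette: dict[str, str],
    contigs: dict[str, Contig],
    *,
    corpus: TargetCorpus | None = None,
) -> list[ProtospacerHit]:
    """Drop pseudospacer pairs whose repeat-length flanks also match the target.

    Gene homology around a pseudospacer shows up as similarity extending
    beyond the pair; such pairs say nothing about chance spacer matching
    and are removed.  A flank truncated by the contig end is used if at
    least half the repeat length remains, else treated as non-matching.
    """
    by_seq: dict[tuple, Pseudospacer] = {
        (p.original.cassette_id, p.original.serial): p for p in pseudospacers
    }
    corpus = corpus or TargetCorpus(contigs)
    flank_matches: dict[str, set[str]] = {}
    kept = []
    for h in pseudo_hits:
        ps = by_seq.get((h.spacer.cassette_id, h.spacer.serial))
        if ps is None:
            raise ValueError("pseudo hit without matching pseudospacer provenance")
        rep_len = len(repeat_of_cassette.get(h.spacer.cassette_id, "")) or FLANK_LEN
        src = contigs[ps.contig_id].sequence
        s, e = ps.interval
        flanks = [src[max(0, s - rep_len) : s], src[e : e + rep_len]]
        contaminated = False
        for flank in flanks:
            if len(flank) < max(1, rep_len // 2):
                continue                      # truncated too short: non-matching
            if flank not in flank_matches:
                flank_matches[flank] = corpus.matched_contigs(
                    flank, contamination_budget(len(flank))
                )
            if h.target_contig_id in flank_matches[flank]:
                contaminated = True
                break
        if not contaminated:
            kept.append(h)
    return kept


# --- PAM ----------------------------------------------------------------

def extract_pam_flanks(
    hits: list[ProtospacerHit],
    cluster_of_cassette: dict[str, str],
) -> list[dict]:
    """Flank table for PAM scanning: one row per reliable hit and side."""
    rows = []
    for h in hits:
        group = cluster_of_cassette.get(h.spacer.cassette_id, "unclustered")
        rows.append({"group": group, "side": "left", "flank": h.flank_left})
        rows.append({"group": group, "side": "right", "flank": h.flank_right})
    return rows


def _column_ic(flanks: list[str], side: str,
               small_sample_correction: bool = True) -> tuple[list[float], list[str]]:
    """Per-position information content; left flanks anchor at the protospacer.

    With few observations the plug-in entropy is biased low, inflating the
    apparent information content (a 2-of-3 majority column already shows
    1.08 raw bits); the standard first-order correction 3/(2 ln2 n) is
    subtracted by default so small groups do not fabricate motifs.
    """
    cols: list[list[str]] = [[] for _ in range(FLANK_LEN)]
    for f in flanks:
        if side == "left":     # right-align: position FLANK_LEN-1 abuts the protospacer
            for i, ch in enumerate(reversed(f)):
                cols[FLANK_LEN - 1 - i].append(ch)
        else:                  # left-align: position 0 abuts the protospacer
            for i, ch in enumerate(f):
                cols[i].append(ch)
    ics, consensus = [], []
    for col in cols:
        obs = [c for c in col if c in "ACGT"]
        if not obs:
            ics.append(0.0)
            consensus.append("-")
            continue
        freqs = np.array([obs.count(b) for b in "ACGT"], dtype=float)
        p = freqs / freqs.sum()
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        ic = 2.0 - entropy
        if small_sample_correction:
            ic -= 3.0 / (2.0 * np.log(2) * len(obs))
        ics.append(float(max(ic, 0.0)))
        consensus.append("ACGT"[int(np.argmax(freqs))])
    return ics, consensus


def pam_scan(
    flank_table: list[dict],
    *,
    min_hits: int = 3,
    ic_threshold: float = 1.0,
    min_run: int = 2,
    small_sample_correction: bool = True,
) -> dict:
    """Position-wise information content per repeat-cluster group and side.

    A motif is reported for a group/side only when at least ``min_run``
    consecutive positions each reach ``ic_threshold`` bits; groups with
    fewer than ``min_hits`` flanks are skipped.  The expected outcome on
    unstructured flanks is "no reliable PAM" everywhere.
    """
    grouped: dict[tuple[str, str], list[str]] = defaultdict(list)
    for row in flank_table:
        grouped[(row["group"], row["side"])].append(row["flank"])
    report: dict = {}
    for (group, side), flanks in sorted(grouped.items()):
        entry = report.setdefault(group, {})
        if len(flanks) < min_hits:
            entry[side] = {"n": len(flanks), "motif": None, "reason": "too_few_hits"}
            continue
        ics, consensus = _column_ic(flanks, side, small_sample_correction)
        motif = None
        run_start, best_run = None, 0
        run = 0
        for i, ic in enumerate(ics):
            if ic >= ic_threshold:
                run += 1
                if run > best_run:
                    best_run, run_start = run, i - run + 1
            else:
                run = 0
        if best_run >= min_run:
            motif = "".join(consensus[run_start : run_start + best_run])
        entry[side] = {
            "n": len(flanks),
            "ic": [round(x, 3) for x in ics],
            "motif": motif,
            "reason": None if motif else "no_reliable_pam",
        }
    return report
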