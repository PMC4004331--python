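"""Cassette candidate construction and the three-rule consensus filter.

Per-program array predictions are merged into candidates by reciprocal
overlap, then filtered: (1) candidates reported by all three detectors are
accepted outright; (2) candidates from one or two detectors are accepted if
a cas gene lies within the adjacency window; (3) remaining candidates whose
repeat consensus clusters with an already-accepted cassette's repeat are
accepted, iterated to a fixed point.  Everything else is rejected.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .repeats import cluster_repeats, consensus_repeat, DEFAULT_CLUSTER_PARAMS
from .types import ArrayPrediction, Cassette, Contig, GeneAnnotation, Interval, Spacer

log = logging.getLogger(__name__)

ALL_THREE = frozenset({"CRT", "CFI", "PIL"})
DEFAULT_CAS_WINDOW = 2000        # nt between cas gene and cassette interval
DEFAULT_COMPLETE_FLANK = 100     # nt of non-cassette sequence required on each side


@dataclass
class BuiltinDetectorParams:
    """Parameters of the minimal exact-chain array detector."""

    repeat_length: tuple[int, int] = (21, 48)
    spacer_gap: tuple[int, int] = (20, 80)
    min_copies: int = 3
    seed_size: int = 16


def detect_arrays_builtin(
    contig: Contig, params: BuiltinDetectorParams | None = None
) -> list[ArrayPrediction]:
    """Minimal repeat-spacer array detector (program label BUILTIN).

    Finds chains of >= min_copies identical seed words at admissible gaps
    and extends each chain to the maximal common repeat across all copies.
    Intended for exact or near-exact repeat copies (the synthetic default);
    it is not a replacement for the dedicated detector programs.
    """
    p = params or BuiltinDetectorParams()
    seq = contig.sequence
    k = p.seed_size
    min_period = p.repeat_length[0] + p.spacer_gap[0]
    max_period = p.repeat_length[1] + p.spacer_gap[1]

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)

    chains: list[list[int]] = []
    for positions in index.values():
        if len(positions) < p.min_copies:
            continue
        run = [positions[0]]
        for q in positions[1:]:
            if min_period <= q - run[-1] <= max_period:
                run.append(q)
            else:
                if len(run) >= p.min_copies:
                    chains.append(run)
                run = [q]
        if len(run) >= p.min_copies:
            chains.append(run)

    # extend each chain to the maximal repeat shared by all copies
    refined: list[tuple[list[Interval], str]] = []
    seen: set[tuple] = set()
    for run in chains:
        diffs = [b - a for a, b in zip(run, run[1:])]
        budget = min(diffs) - k - p.spacer_gap[0]   # total extension allowed
        max_ext = min(budget, p.repeat_length[1] - k)
        left = 0
        while (
            left < max_ext
            and run[0] - left - 1 >= 0
            and len({seq[q - left - 1] for q in run}) == 1
        ):
            left += 1
        right = 0
        while (
            left + right < max_ext
            and run[-1] + k + right < len(seq)
            and len({seq[q + k + right] for q in run}) == 1
        ):
            right += 1
        rep_len = k + left + right
        if not p.repeat_length[0] <= rep_len <= p.repeat_length[1]:
            continue
        if any(not p.spacer_gap[0] <= d - rep_len <= p.spacer_gap[1] for d in diffs):
            continue
        intervals = [(q - left, q - left + rep_len) for q in run]
        key = tuple(intervals)
        if key not in seen:
            seen.add(key)
            refined.append((intervals, seq[run[0] - left : run[0] - left + rep_len]))

    # greedy selection: most copies, then longest span, then leftmost
    refined.sort(key=lambda t: (-len(t[0]), t[0][0][0] - t[0][-1][1], t[0][0][0]))
    accepted: list[tuple[list[Interval], str]] = []
    taken: list[Interval] = []
    for intervals, _rep in refined:
        lo, hi = intervals[0][0], intervals[-1][1]
        if any(lo < te and ts < hi for ts, te in taken):
            continue
        taken.append((lo, hi))
        accepted.append((intervals, _rep))

    predictions = []
    for n, (intervals, _rep) in enumerate(sorted(accepted, key=lambda t: t[0][0][0]), 1):
        copies = [seq[s:e] for s, e in intervals]
        predictions.append(ArrayPrediction(
            contig_id=contig.id,
            program="BUILTIN",
            array_id=f"{contig.id}.builtin{n}",
            repeat_intervals=intervals,
            repeat_consensus=consensus_repeat(copies),
        ))
    return predictions


@dataclass
class CandidateCassette:
    """Per-program predictions of the same array, merged."""

    contig_id: str
    interval: Interval
    programs: frozenset[str]
    best_prediction: ArrayPrediction
    members: list[ArrayPrediction] = field(default_factory=list)
    cas_adjacent: bool = False


def _reciprocal_overlap(a: Interval, b: Interval, threshold: float) -> bool:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    return ov > 0 and ov >= threshold * (a[1] - a[0]) and ov >= threshold * (b[1] - b[0])


def merge_predictions(
    predictions: list[ArrayPrediction], *, overlap: float = 0.5
) -> list[CandidateCassette]:
    """Group per-program predictions into candidates by reciprocal overlap.

    Predictions whose array intervals reciprocally overlap by >= ``overlap``
    are single-linkage grouped; the candidate interval is the union and the
    defining prediction is the member with the most repeat copies (ties:
    longest array, then leftmost).
    """
    by_contig: dict[str, list[ArrayPrediction]] = defaultdict(list)
    for pred in predictions:
        by_contig[pred.contig_id].append(pred)

    candidates = []
    for contig_id in sorted(by_contig):
        preds = sorted(by_contig[contig_id], key=lambda p: (p.interval, p.program))
        parent = list(range(len(preds)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(preds)):
            for j in range(i + 1, len(preds)):
                if _reciprocal_overlap(preds[i].interval, preds[j].interval, overlap):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)

        groups: dict[int, list[ArrayPrediction]] = defaultdict(list)
        for i, pred in enumerate(preds):
            groups[find(i)].append(pred)
        for root in sorted(groups):
            members = groups[root]
            lo = min(p.interval[0] for p in members)
            hi = max(p.interval[1] for p in members)
            best = max(
                members,
                key=lambda p: (p.n_repeats, p.interval[1] - p.interval[0], -p.interval[0]),
            )
            candidates.append(CandidateCassette(
                contig_id=contig_id,
                interval=(lo, hi),
                programs=frozenset(p.program for p in members),
                best_prediction=best,
                members=members,
            ))
    return candidates


def _cas_near(candidate: CandidateCassette, genes: list[GeneAnnotation], window: int) -> bool:
    cs, ce = candidate.interval
    for g in genes:
        if g.contig_id != candidate.contig_id:
            continue
        gs, ge = g.interval
        gap = max(cs - ge, gs - ce, 0)
        if gap <= window:
            return True
    return False


def _build_cassette(
    candidate: CandidateCassette,
    rule: str,
    contigs: dict[str, Contig] | None,
    complete_flank: int,
) -> Cassette:
    pred = candidate.best_prediction
    cid = f"{candidate.contig_id}_{pred.interval[0]}_{pred.interval[1]}"
    seq = contigs[candidate.contig_id].sequence if contigs else None
    spacers = []
    for idx, (s, e) in enumerate(pred.spacer_intervals, 1):
        spacers.append(Spacer(
            cassette_id=cid,
            serial=idx,
            interval=(s, e),
            sequence=seq[s:e] if seq else "",
            provisional=True,
        ))
    if seq is not None:
        copies = [seq[s:e] for s, e in pred.repeat_intervals]
        consensus = consensus_repeat(copies)
        lo, hi = pred.interval
        complete = lo >= complete_flank and len(seq) - hi >= complete_flank
    else:
        consensus = pred.repeat_consensus
        complete = False
    return Cassette(
        id=cid,
        contig_id=candidate.contig_id,
        interval=pred.interval,
        repeat_intervals=list(pred.repeat_intervals),
        spacers=spacers,
        repeat_consensus=consensus,
        programs=candidate.programs,
        acceptance_rule=rule,
        cas_adjacent=candidate.cas_adjacent,
        complete=complete,
    )


def consensus_filter(
    candidates: list[CandidateCassette],
    cas_annotations: list[GeneAnnotation],
    contigs: dict[str, Contig] | None = None,
    *,
    cas_window: int = DEFAULT_CAS_WINDOW,
    cluster_params: tuple[float, float, int] = DEFAULT_CLUSTER_PARAMS,
    complete_flank: int = DEFAULT_COMPLETE_FLANK,
) -> list[Cassette]:
    """Apply the three acceptance rules and return the accepted cassette set.

    Rule priority is 1 > 2 > 3: a candidate reported by all three programs
    is recorded as ``all_three`` even when it also sits next to a cas gene
    (the ``cas_adjacent`` flag still records the adjacency).  Rule 3 is
    iterated to a fixed point, so a chain of repeat-similar candidates can
    be pulled in through an intermediate acceptance.
    """
    for cand in candidates:
        cand.cas_adjacent = _cas_near(cand, cas_annotations, cas_window)

    accepted: list[tuple[CandidateCassette, str]] = []
    remaining: list[CandidateCassette] = []
    for cand in candidates:
        if ALL_THREE <= cand.programs:
            accepted.append((cand, "all_three"))
        elif cand.cas_adjacent:
            accepted.append((cand, "cas_adjacent"))
        else:
            remaining.append(cand)

    # rule 3 to a fixed point
    while remaining and accepted:
        consensi = {}
        acc_keys = set()
        for idx, (cand, _) in enumerate(accepted):
            key = f"a{idx}"
            acc_keys.add(key)
            consensi[key] = cand.best_prediction.repeat_consensus
        rem_key = {f"r{idx}": cand for idx, cand in enumerate(remaining)}
        consensi.update({k: c.best_prediction.repeat_consensus for k, c in rem_key.items()})
        clusters = cluster_repeats(consensi, cluster_params)
        pulled: set[str] = set()
        for cl in clusters:
            if cl.member_cassette_ids & acc_keys:
                pulled |= {m for m in cl.member_cassette_ids if m.startswith("r")}
        if not pulled:
            break
        for key in sorted(pulled):
            accepted.append((rem_key[key], "repeat_similar"))
        remaining = [c for k, c in rem_key.items() if k not in pulled]

    cassettes = [
        _build_cassette(cand, rule, contigs, complete_flank) for cand, rule in accepted
    ]
    cassettes.sort(key=lambda c: (c.contig_id, c.interval))
    return cassettes


def extract_spacers(
    cassettes: list[Cassette],
    dataset_of: dict[str, str] | None = None,
) -> tuple[list[Spacer], dict]:
    """Collect spacers from accepted cassettes with a uniqueness summary.

    Uniqueness is computed on the canonical (strand-insensitive) sequence.
    Repeat-only cassettes contribute nothing and are logged.  When
    ``dataset_of`` maps cassette id -> dataset, per-dataset totals are
    included in the summary.
    """
    spacers: list[Spacer] = []
    for cassette in cassettes:
        if not cassette.spacers:
            log.warning("cassette %s has no spacers (repeat-only); excluded", cassette.id)
            continue
        spacers.extend(cassette.spacers)

    summary: dict = {
        "total": len(spacers),
        "unique": len({sp.canonical_sequence for sp in spacers}),
    }
    if dataset_of:
        per: dict[str, dict] = {}
        for sp in spacers:
            ds = dataset_of.get(sp.cassette_id, "other")
            per.setdefault(ds, []).append(sp.canonical_sequence)
        summary["per_dataset"] = {
            ds: {"total": len(seqs), "unique": len(set(seqs))} for ds, seqs in per.items()
        }
    return spacers, summary
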