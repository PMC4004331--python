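"""End-to-end orchestration: predictions -> cassettes -> protospacers -> stats.

Thin composition of the per-stage modules, so drivers, tests and the
acceptance machinery run the identical path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calling import (
    CandidateCassette,
    consensus_filter,
    extract_spacers,
    merge_predictions,
)
from .protospacer import (
    make_pseudospacers,
    pseudo_flank_filter,
    reliable_hits,
    repeat_contamination_filter,
    scan_targets,
)
from .matcher import TargetCorpus
from .repeats import cluster_repeats, orient_cassettes
from .stats import classify_spacers
from .types import ArrayPrediction, Cassette, Contig, GeneAnnotation, ProtospacerHit, Spacer


@dataclass
class PipelineResult:
    candidates: list[CandidateCassette]
    cassettes: list[Cassette]
    clusters: list
    spacers: list[Spacer]
    spacer_summary: dict
    hits: list[ProtospacerHit] = field(default_factory=list)
    reliable: list[ProtospacerHit] = field(default_factory=list)
    targeting: set = field(default_factory=set)
    shared: set = field(default_factory=set)

    @property
    def individual_of_cassette(self) -> dict[str, str]:
        return self._ind_of_cassette

    @property
    def individual_of_contig(self) -> dict[str, str]:
        return self._ind_of_contig

    @property
    def cassette_intervals(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for c in self.cassettes:
            out.setdefault(c.contig_id, []).append(c.interval)
        # candidate intervals count too: rejected candidates may still be
        # genuine arrays, and spacer windows inside them are not protospacers
        for cand in self.candidates:
            out.setdefault(cand.contig_id, []).append(cand.interval)
        return out


def run_pipeline(
    contigs: dict[str, Contig],
    predictions: list[ArrayPrediction],
    cas_annotations: list[GeneAnnotation],
    *,
    scan: bool = True,
    max_mismatches: int = 4,
) -> PipelineResult:
    """Run candidate merging, filtering, clustering, orientation and
    (optionally) the protospacer scan with the repeat-contamination filter."""
    candidates = merge_predictions(predictions)
    cassettes = consensus_filter(candidates, cas_annotations, contigs)
    consensi = {c.id: c.repeat_consensus for c in cassettes}
    clusters = cluster_repeats(consensi) if consensi else []
    orient_cassettes(cassettes, cas_annotations, clusters)
    spacers, summary = extract_spacers(cassettes)

    result = PipelineResult(
        candidates=candidates,
        cassettes=cassettes,
        clusters=clusters,
        spacers=spacers,
        spacer_summary=summary,
    )
    result._ind_of_contig = {cid: c.individual_id for cid, c in contigs.items()}
    contig_of_cassette = {c.id: c.contig_id for c in cassettes}
    result._ind_of_cassette = {
        cid: result._ind_of_contig[ctg] for cid, ctg in contig_of_cassette.items()
    }

    if scan and spacers:
        intervals = result.cassette_intervals
        corpus = TargetCorpus(contigs)
        result._corpus = corpus
        hits = scan_targets(
            spacers,
            contigs,
            intervals,
            max_mismatches=max_mismatches,
            individual_of_cassette=result._ind_of_cassette,
            corpus=corpus,
        )
        repeat_of = {c.id: c.repeat_consensus for c in cassettes}
        repeat_contamination_filter(hits, repeat_of, contigs, intervals, corpus=corpus)
        result.hits = hits
        result.reliable = reliable_hits(hits, max_mismatches)
        result.targeting, result.shared = classify_spacers(
            spacers, result.reliable, result._ind_of_cassette, result._ind_of_contig
        )
    return result


def pseudospacer_null(
    result: PipelineResult,
    contigs: dict[str, Contig],
    seed: int,
    *,
    max_mismatches: int = 4,
):
    """Pseudospacer hit discovery with the flank contamination filter applied.

    Returns (pseudospacers, raw pseudo hits, surviving pseudo pairs).
    """
    corpus = getattr(result, "_corpus", None) or TargetCorpus(contigs)
    contig_of_cassette = {c.id: c.contig_id for c in result.cassettes}
    intervals = result.cassette_intervals
    pseudos = make_pseudospacers(
        result.spacers,
        contigs,
        intervals,
        contig_of_cassette,
        result.individual_of_contig,
        seed,
    )
    pseudo_spacers = [p.as_spacer() for p in pseudos]
    hits = scan_targets(
        pseudo_spacers,
        contigs,
        intervals,
        max_mismatches=max_mismatches,
        individual_of_cassette=result.individual_of_cassette,
        corpus=corpus,
    )
    # a pseudospacer trivially matches the very window it was drawn from;
    # that self-hit is its source locus, not a pseudo-protospacer
    source_of = {(p.original.cassette_id, p.original.serial): (p.contig_id, p.interval)
                 for p in pseudos}
    hits = [
        h for h in hits
        if source_of.get((h.spacer.cassette_id, h.spacer.serial))
        != (h.target_contig_id, h.target_interval)
    ]
    repeat_of = {c.id: c.repeat_consensus for c in result.cassettes}
    repeat_contamination_filter(hits, repeat_of, contigs, intervals, corpus=corpus)
    surviving = pseudo_flank_filter(
        reliable_hits(hits, max_mismatches), pseudos, repeat_of, contigs, corpus=corpus
    )
    return pseudos, hits, surviving
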