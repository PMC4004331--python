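"""Rule-based taxonomic labelling of contigs from ranked hit tables.

The rules formalise a curation protocol for short metagenomic contigs:
a phylum label requires unanimity of the top ten hits; deeper labels
(class, family, genus) require a strict majority of the top thirty; and a
taxonomically diverse but clearly bacterial hit list yields the
nonspecific label "Bacteria".  Protospacer-containing contigs of phage or
plasmid origin transfer their host's taxonomy instead of their own.
"""

from __future__ import annotations

import csv
from collections import Counter
from pathlib import Path

from .types import TaxonHit, TaxonomyLabel

_SUB_RANKS = ("genus", "family", "class")   # deepest first
_RANK_ATTR = {"genus": "genus", "family": "family", "class": "class_"}


def _majority(values: list[str]) -> str | None:
    """Strict-majority value (> half of all entries, missing ones included)."""
    present = [v for v in values if v]
    if not present:
        return None
    value, count = Counter(present).most_common(1)[0]
    return value if count > len(values) / 2 else None


def assign_contig_taxon(hits: list[TaxonHit]) -> TaxonomyLabel:
    """Assign the deepest defensible taxonomic label from ranked hits.

    ``hits`` must be sorted by descending score (rank_index 1..n) and
    pre-filtered upstream to a sensible e-value.  Genus, family and class
    need a strict majority of the top 30 hits (or of all hits when fewer
    exist); phylum needs unanimity of the top 10.  Diverse but all-bacterial
    hits get the nonspecific domain label; otherwise no label is assigned.
    """
    if not hits:
        return TaxonomyLabel(rank="none", reason="no_hits")
    ranked = sorted(hits, key=lambda h: h.rank_index)
    top30 = ranked[:30]
    top10 = ranked[:10]

    phyla10 = {h.phylum for h in top10 if h.phylum}
    phylum_ctx = phyla10.pop() if len(phyla10) == 1 and all(h.phylum for h in top10) else ""

    for rank in _SUB_RANKS:
        attr = _RANK_ATTR[rank]
        winner = _majority([getattr(h, attr) for h in top30])
        if winner is not None:
            return TaxonomyLabel(rank=rank, name=winner, reason="top30_majority",
                                 phylum=phylum_ctx)
    if phylum_ctx:
        return TaxonomyLabel(rank="phylum", name=phylum_ctx, reason="top10_phylum",
                             phylum=phylum_ctx)
    if all(h.origin == "bacterial" for h in ranked):
        return TaxonomyLabel(rank="domain_nonspecific", reason="diverse")
    return TaxonomyLabel(rank="none", reason="diverse")


def taxon_vote_audit(hits: list[TaxonHit]) -> dict:
    """Majority shares per rank over the top 30 hits, for audit alongside a call."""
    ranked = sorted(hits, key=lambda h: h.rank_index)[:30]
    audit = {}
    for rank in _SUB_RANKS:
        attr = _RANK_ATTR[rank]
        values = [getattr(h, attr) for h in ranked if getattr(h, attr)]
        if values:
            value, count = Counter(values).most_common(1)[0]
            audit[rank] = {"top": value, "share": count / len(ranked)}
        else:
            audit[rank] = {"top": None, "share": 0.0}
    return audit


def transfer_protospacer_taxon(
    target_label: TaxonomyLabel,
    origin: str,
    host: str,
    host_taxa: dict[str, TaxonomyLabel],
) -> TaxonomyLabel:
    """Taxonomy for a spacer, transferred from its protospacer's contig.

    Phage and plasmid protospacers inherit the *host's* label (the spacer
    was acquired by the host, not the mobile element); bacterial
    protospacers use the contig's own label.  A phage with an unknown host
    yields no label.
    """
    if origin in ("phage", "plasmid"):
        if host and host in host_taxa:
            return host_taxa[host]
        return TaxonomyLabel(rank="none", reason="unknown_host")
    return target_label


def _phylum_of(label: TaxonomyLabel) -> str:
    if label.rank == "phylum":
        return label.name
    return label.phylum


def compare_labels(flank_label: TaxonomyLabel, proto_label: TaxonomyLabel) -> str:
    """Compare flank-based and protospacer-based assignments of one contig.

    Returns ``concordant_at_phylum`` when the phyla agree, ``refines`` when
    one label is nonspecific and the other specific, ``conflicts`` for
    different phyla, and ``incomparable`` when either label is absent (or
    both are nonspecific).
    """
    if flank_label.rank == "none" or proto_label.rank == "none":
        return "incomparable"
    a_ns = flank_label.rank == "domain_nonspecific"
    b_ns = proto_label.rank == "domain_nonspecific"
    if a_ns and b_ns:
        return "incomparable"
    if a_ns or b_ns:
        return "refines"
    pa, pb = _phylum_of(flank_label), _phylum_of(proto_label)
    if pa and pb:
        return "concordant_at_phylum" if pa == pb else "conflicts"
    return "incomparable"


def read_taxon_hits_tsv(path: str | Path) -> dict[str, list[TaxonHit]]:
    """Read ranked hit tables: contig_id, rank, score, phylum, class, family,
    genus, origin, host (one row per hit)."""
    out: dict[str, list[TaxonHit]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["contig_id"], []).append(TaxonHit(
                rank_index=int(row["rank"]),
                score=float(row.get("score", 0) or 0),
                phylum=row.get("phylum", ""),
                class_=row.get("class", ""),
                family=row.get("family", ""),
                genus=row.get("genus", ""),
                origin=row.get("origin", "bacterial") or "bacterial",
                host=row.get("host", ""),
            ))
    for hits in out.values():
        hits.sort(key=lambda h: h.rank_index)
    return out
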