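#!/usr/bin/env python
"""Scan spacers against the metagenome, filter, and run the pseudospacer null.

Full-length both-strand Hamming scan at <=4 mismatches with cassette-window
exclusion and the repeat-contamination filter; then every spacer is
replaced by a random same-length fragment and rescanned, with the
repeat-length flank filter removing homology-context pairs.  Also runs the
PAM scan on the reliable hits grouped by repeat cluster.
"""

import argparse
import json
from pathlib import Path

from gutcrispr import io as gio
from gutcrispr.pipeline import pseudospacer_null, run_pipeline
from gutcrispr.protospacer import extract_pam_flanks, pam_scan

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=3)
    args = ap.parse_args()

    contigs = gio.read_fasta(args.sim / "contigs.fasta")
    predictions = gio.ingest_predictions_tsv(args.sim / "predictions.tsv", contigs)
    cas = gio.read_cas_tsv(args.sim / "cas.tsv")
    res = run_pipeline(contigs, predictions, cas)

    with open(args.out / "protospacer_hits.tsv", "w") as fh:
        fh.write("cassette_id\tserial\tspacer_individual\ttarget_contig\tstart\tend\t"
                 "strand\tmismatches\tflank_left\tflank_right\tpassed_repeat_filter\n")
        for h in res.hits:
            fh.write(f"{h.spacer.cassette_id}\t{h.spacer.serial}\t{h.spacer_individual}\t"
                     f"{h.target_contig_id}\t{h.target_interval[0]}\t{h.target_interval[1]}\t"
                     f"{h.strand}\t{h.mismatches}\t{h.flank_left}\t{h.flank_right}\t"
                     f"{h.passed_repeat_filter}\n")

    pseudos, raw, surviving = pseudospacer_null(res, contigs, seed=args.seed)

    cluster_of = {cid: cl.id for cl in res.clusters for cid in cl.member_cassette_ids}
    pam = pam_scan(extract_pam_flanks(res.reliable, cluster_of))
    n_motifs = sum(1 for g in pam.values() for s in g.values() if s.get("motif"))
    (args.out / "pam_report.json").write_text(json.dumps(pam, indent=1))

    null_summary = {
        "n_spacers": len(res.spacers),
        "n_hits": len(res.hits),
        "n_reliable_hits": len(res.reliable),
        "n_targeting_spacers": len(res.targeting),
        "n_shared_spacers": len(res.shared),
        "n_pseudospacers": len(pseudos),
        "n_pseudo_raw_hits": len(raw),
        "n_pseudo_pairs_surviving": len(surviving),
        "n_pam_motifs": n_motifs,
        "seed": args.seed,
    }
    (args.out / "pseudospacer_null.json").write_text(json.dumps(null_summary, indent=1))

    print(f"{len(res.spacers)} spacers -> {len(res.hits)} hits, "
          f"{len(res.reliable)} reliable")
    print(f"targeting spacers: {len(res.targeting)}; shared spacers: {len(res.shared)}")
    print(f"pseudospacer null: {len(pseudos)} pseudospacers, {len(raw)} raw hits, "
          f"{len(surviving)} pairs survive the flank filter")
    print(f"PAM motifs over repeat-cluster groups: {n_motifs}")
    print(f"wrote {args.out}/protospacer_hits.tsv, pseudospacer_null.json, pam_report.json")


if __name__ == "__main__":
    main()
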