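#!/usr/bin/env python
"""Merge detector predictions and apply the three-rule consensus filter.

Accepts cassettes reported by all three detectors, single/double-detector
candidates next to cas genes, and candidates whose repeat clusters with an
already-accepted cassette; writes the accepted set as GFF3 plus a per-rule
summary.
"""

import argparse
from collections import Counter
from pathlib import Path

from gutcrispr import io as gio
from gutcrispr.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    contigs = gio.read_fasta(args.sim / "contigs.fasta")
    predictions = gio.ingest_predictions_tsv(args.sim / "predictions.tsv", contigs)
    cas = gio.read_cas_tsv(args.sim / "cas.tsv")

    res = run_pipeline(contigs, predictions, cas, scan=False)
    gio.write_cassette_gff(res.cassettes, args.out / "cassettes.gff3")
    with open(args.out / "cassette_report.tsv", "w") as fh:
        fh.write("cassette_id\tcontig_id\tstart\tend\trule\tprograms\tn_spacers\tcomplete\n")
        for c in res.cassettes:
            fh.write(f"{c.id}\t{c.contig_id}\t{c.interval[0]}\t{c.interval[1]}\t"
                     f"{c.acceptance_rule}\t{','.join(sorted(c.programs))}\t"
                     f"{c.n_spacers}\t{c.complete}\n")

    rules = Counter(c.acceptance_rule for c in res.cassettes)
    print(f"{len(res.candidates)} merged candidates -> {len(res.cassettes)} accepted")
    for rule, n in sorted(rules.items()):
        print(f"  {rule}: {n}")
    print(f"spacers: {res.spacer_summary['total']} total, "
          f"{res.spacer_summary['unique']} unique (canonical form)")
    print(f"wrote {args.out}/cassettes.gff3, cassette_report.tsv")


if __name__ == "__main__":
    main()
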