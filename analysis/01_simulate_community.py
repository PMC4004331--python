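#!/usr/bin/env python
"""Generate the synthetic study community.

Writes a multi-individual contig set with planted CRISPR arrays, cas loci,
phage-borne protospacers, cross-individual spacer sharing and decoy
repeats, plus simulated CRT/CRISPRFinder/PILER-CR predictions, under
results/sim/.
"""

import argparse
from pathlib import Path

from gutcrispr import io as gio
from gutcrispr.simulate import (
    DetectorAgreement,
    SimulationConfig,
    emit_detector_predictions,
    generate_community,
)

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "sim")
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, n_decoys=6)
    contigs, cas, truth = generate_community(cfg)
    predictions = emit_detector_predictions(
        contigs, truth, DetectorAgreement(), seed=args.seed + 1
    )

    args.out.mkdir(parents=True, exist_ok=True)
    gio.write_fasta(contigs, args.out / "contigs.fasta")
    gio.write_predictions_tsv(predictions, args.out / "predictions.tsv")
    gio.write_cas_tsv(cas, args.out / "cas.tsv")
    truth.to_json(args.out / "manifest.json")

    n_shared = len(truth.shared_groups)
    print(f"community: {len(contigs)} contigs across {cfg.n_individuals} individuals")
    print(f"planted: {len(truth.cassettes)} cassettes, "
          f"{sum(len(c.spacer_serials) for c in truth.cassettes)} spacers, "
          f"{len(truth.protospacers)} protospacers, "
          f"{n_shared} shared-spacer groups, {len(truth.decoys)} decoys")
    print(f"detector predictions: {len(predictions)}")
    print(f"wrote {args.out}/contigs.fasta, predictions.tsv, cas.tsv, manifest.json")


if __name__ == "__main__":
    main()
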