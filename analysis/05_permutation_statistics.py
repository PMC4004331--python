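#!/usr/bin/env python
"""The three permutation analyses on the synthetic community.

Spacer-position Monte-Carlo test (targeting spacers vs the leader end and
shared spacers vs the trailer end), the cassette-shuffle sharing test, and
the Cochran-Mantel-Haenszel co-occurrence test on the per-individual pair
matrix with its protospacer-shuffle null.
"""

import argparse
import json
from pathlib import Path

from gutcrispr import io as gio
from gutcrispr.pipeline import run_pipeline
from gutcrispr.stats import (
    build_pair_matrix,
    cmh_permutation_test,
    cmh_statistic,
    majority_foreign_count,
    position_permutation_test,
    sharing_permutation_test,
    write_pair_matrix_tsv,
)

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=5)
    ap.add_argument("--n-perm", type=int, default=20_000)
    args = ap.parse_args()

    contigs = gio.read_fasta(args.sim / "contigs.fasta")
    predictions = gio.ingest_predictions_tsv(args.sim / "predictions.tsv", contigs)
    cas = gio.read_cas_tsv(args.sim / "cas.tsv")
    res = run_pipeline(contigs, predictions, cas)

    report = {}

    pos_t = position_permutation_test(
        res.cassettes, res.targeting, tail="lower",
        n_perm=args.n_perm, seed=args.seed,
    )
    report["position_targeting"] = {
        "observed_serial_sum": pos_t.observed, "null_mean": pos_t.null_mean,
        "null_sd": pos_t.null_sd, "p_lower": pos_t.p_value, "n_perm": pos_t.n_perm,
    }
    try:
        pos_s = position_permutation_test(
            res.cassettes, res.shared, tail="upper",
            n_perm=args.n_perm, seed=args.seed + 1,
        )
        report["position_shared"] = {
            "observed_serial_sum": pos_s.observed, "null_mean": pos_s.null_mean,
            "p_upper": pos_s.p_value, "n_perm": pos_s.n_perm,
        }
    except ValueError as exc:
        report["position_shared"] = {"skipped": str(exc)}

    ind_of_cassette = res.individual_of_cassette
    share = sharing_permutation_test(
        [ind_of_cassette[c.id] for c in res.cassettes],
        [[sp.canonical_sequence for sp in c.spacers] for c in res.cassettes],
        n_perm=args.n_perm, seed=args.seed + 2, tail="lower",
    )
    report["sharing"] = {
        "observed_shared": share.observed, "null_mean": share.null_mean,
        "null_sd": share.null_sd, "p_lower": share.p_value, "n_perm": share.n_perm,
    }

    individuals = sorted({c.individual_id for c in contigs.values()})
    matrix = build_pair_matrix(res.reliable, individuals, res.individual_of_contig)
    write_pair_matrix_tsv(matrix, args.out / "pair_matrix.tsv")
    cmh_p = cmh_permutation_test(matrix, n_perm=10_000, seed=args.seed + 3)
    report["cmh"] = {
        "statistic_uncorrected": cmh_statistic(matrix),
        "statistic_corrected": cmh_statistic(matrix, continuity_correction=True),
        "p_upper_shuffle": cmh_p.p_value,
        "n_pairs": matrix.total_pairs,
        "majority_foreign": majority_foreign_count(matrix),
    }

    (args.out / "permutation_statistics.json").write_text(
        json.dumps(report, indent=1) + "\n"
    )
    print(json.dumps(report, indent=1))
    print(f"wrote {args.out}/permutation_statistics.json, pair_matrix.tsv")


if __name__ == "__main__":
    main()
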