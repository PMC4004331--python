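#!/usr/bin/env python
"""Cluster repeat consensi, orient cassettes, and assign cas system types.

Orientation comes from adjacent cas loci first, then propagates through
repeat clusters under the shared-strand assumption; spacer serials are
renumbered from the leader.
"""

import argparse
from collections import Counter, defaultdict
from pathlib import Path

from gutcrispr import io as gio
from gutcrispr.repeats import assign_cas_type, cluster_repeats, orient_cassettes

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    cassettes = gio.read_cassette_gff(args.out / "cassettes.gff3")
    cas = gio.read_cas_tsv(args.sim / "cas.tsv")

    clusters = cluster_repeats({c.id: c.repeat_consensus for c in cassettes})
    with open(args.out / "repeat_clusters.tsv", "w") as fh:
        fh.write("cluster_id\tcassette_id\n")
        for cl in clusters:
            for m in sorted(cl.member_cassette_ids):
                fh.write(f"{cl.id}\t{m}\n")

    orient_cassettes(cassettes, cas, clusters)
    gio.write_cassette_gff(cassettes, args.out / "cassettes_oriented.gff3")

    cas_by_contig = defaultdict(list)
    for g in cas:
        cas_by_contig[g.contig_id].append(g)
    calls = []
    with open(args.out / "cas_types.tsv", "w") as fh:
        fh.write("cassette_id\ttype\tevidence\n")
        for c in cassettes:
            near = [g for g in cas_by_contig[c.contig_id]
                    if max(c.interval[0] - g.interval[1],
                           g.interval[0] - c.interval[1], 0) <= 2000]
            call = assign_cas_type(c.id, near)
            calls.append(call)
            fh.write(f"{c.id}\t{call.type}\t{','.join(call.evidence)}\n")

    n_multi = sum(len(cl.member_cassette_ids) > 1 for cl in clusters)
    oriented = sum(c.leader_end != "unknown" for c in cassettes)
    print(f"{len(cassettes)} cassettes in {len(clusters)} repeat clusters "
          f"({n_multi} with >1 member)")
    print(f"oriented {oriented}/{len(cassettes)} cassettes")
    for t, n in sorted(Counter(c.type for c in calls).items()):
        print(f"  cas type {t}: {n}")
    print(f"wrote {args.out}/repeat_clusters.tsv, cassettes_oriented.gff3, cas_types.tsv")


if __name__ == "__main__":
    main()
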