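"""Readers and writers for the external formats the pipeline touches.

Supported formats: contig FASTA (with a ``contig|individual`` header
convention or a sidecar manifest TSV), the normalised array-prediction
exchange TSV, 12-column BLAST tabular, cassette GFF3, cas-annotation TSV,
and the cohort manifests bundled with the package.

Every on-disk coordinate system is converted to the internal 0-based
half-open convention here and nowhere else.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import SeqIO

from ._seq import validate_dna
from .types import ArrayPrediction, Cassette, Contig, GeneAnnotation, Individual, Spacer

log = logging.getLogger(__name__)

_PROGRAM_ALIASES = {
    "CRT": "CRT",
    "CFI": "CFI",
    "CRISPRFINDER": "CFI",
    "PIL": "PIL",
    "PILER": "PIL",
    "PILER-CR": "PIL",
    "BUILTIN": "BUILTIN",
}


def normalize_program(label: str) -> str:
    """Map a detector label onto the canonical program vocabulary."""
    prog = _PROGRAM_ALIASES.get(label.strip().upper())
    if prog is None:
        log.warning("unknown prediction program %r, mapped to OTHER", label)
        return "OTHER"
    return prog


def read_manifest(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a contig manifest TSV: contig_id -> (individual_id, dataset)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["contig_id"]] = (row["individual_id"], row.get("dataset", "other"))
    return out


def read_fasta(
    path: str | Path,
    manifest: dict[str, tuple[str, str]] | None = None,
    *,
    strict: bool = True,
) -> dict[str, Contig]:
    """Read contigs from FASTA, assigning each to an individual.

    The individual comes from ``manifest`` when given, else from a
    ``contig|individual`` header convention; headers without either are an
    error in strict mode and are assigned individual ``"unknown"`` otherwise.
    Sequences are upper-cased; characters outside {A,C,G,T,N} raise in
    strict mode and are mapped to N otherwise.
    """
    contigs: dict[str, Contig] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        header = rec.id
        if manifest is not None and header in manifest:
            cid, individual = header, manifest[header][0]
        elif "|" in header:
            cid, individual = header.split("|", 1)[0], header.split("|", 1)[1]
        elif manifest is not None or strict:
            raise ValueError(f"contig {header!r}: no individual in manifest or header")
        else:
            cid, individual = header, "unknown"
        if cid in contigs:
            raise ValueError(f"duplicate contig id {cid!r}")
        seq = validate_dna(str(rec.seq), strict=strict)
        contigs[cid] = Contig(id=cid, individual_id=individual, sequence=seq)
    if n == 0:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs, path: str | Path, *, with_individual: bool = True) -> None:
    with open(path, "w") as fh:
        it = contigs.values() if isinstance(contigs, dict) else contigs
        for c in it:
            header = f"{c.id}|{c.individual_id}" if with_individual else c.id
            fh.write(f">{header}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")


def ingest_predictions_tsv(
    path: str | Path, contigs: dict[str, Contig] | None = None
) -> list[ArrayPrediction]:
    """Read the normalised array-prediction exchange TSV.

    One row per repeat copy; columns ``contig_id, program, array_id,
    repeat_start, repeat_end, consensus`` with 1-based inclusive
    coordinates on disk.  Rows are grouped by (contig_id, program,
    array_id); conversion to 0-based half-open happens here.
    """
    groups: dict[tuple[str, str, str], list[dict]] = defaultdict(list)
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"contig_id", "program", "array_id", "repeat_start", "repeat_end", "consensus"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"prediction TSV must carry columns {sorted(required)}")
        for row in reader:
            key = (row["contig_id"], normalize_program(row["program"]), row["array_id"])
            groups[key].append(row)

    predictions = []
    for (contig_id, program, array_id), rows in groups.items():
        intervals = sorted(
            (int(r["repeat_start"]) - 1, int(r["repeat_end"])) for r in rows
        )
        if contigs is not None and contig_id in contigs:
            clen = contigs[contig_id].length
            for s, e in intervals:
                if not 0 <= s < e <= clen:
                    raise ValueError(
                        f"array {array_id} on {contig_id}: repeat [{s},{e}) exceeds "
                        f"contig length {clen}"
                    )
        predictions.append(
            ArrayPrediction(
                contig_id=contig_id,
                program=program,
                array_id=array_id,
                repeat_intervals=intervals,
                repeat_consensus=validate_dna(rows[0]["consensus"]),
            )
        )
    return predictions


def write_predictions_tsv(predictions: list[ArrayPrediction], path: str | Path) -> None:
    """Inverse of :func:`ingest_predictions_tsv` (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("contig_id\tprogram\tarray_id\trepeat_start\trepeat_end\tconsensus\n")
        for p in predictions:
            for s, e in p.repeat_intervals:
                fh.write(
                    f"{p.contig_id}\t{p.program}\t{p.array_id}\t{s + 1}\t{e}\t{p.repeat_consensus}\n"
                )


@dataclass
class BlastHit:
    """A raw 12-column BLAST tabular row, coordinates normalised.

    ``subject_interval`` is 0-based half-open on the subject plus strand;
    ``strand`` records the original orientation (sstart > send -> "-").
    Query coordinates stay 1-based inclusive in query space, as emitted.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_interval: tuple[int, int]
    strand: str
    evalue: float
    bitscore: float

    @property
    def gapped(self) -> bool:
        return self.gap_opens > 0


def ingest_blast_tab(path: str | Path) -> list[BlastHit]:
    """Read BLAST outfmt-6-style tabular output."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                sstart, send = int(cols[8]), int(cols[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if sstart <= send:
                strand, interval = "+", (sstart - 1, send)
            else:
                strand, interval = "-", (send - 1, sstart)
            hits.append(
                BlastHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    align_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    query_start=int(cols[6]),
                    query_end=int(cols[7]),
                    subject_interval=interval,
                    strand=strand,
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            )
    if not hits:
        log.warning("no hits parsed from %s", path)
    return hits


def read_cas_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Read cas-gene annotations: contig_id, gene, start, end (1-based incl.), strand."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                GeneAnnotation(
                    contig_id=row["contig_id"],
                    name=row["gene"].strip().lower(),
                    interval=(int(row["start"]) - 1, int(row["end"])),
                    strand=row.get("strand", "+"),
                )
            )
    return out


def write_cas_tsv(genes: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tgene\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.contig_id}\t{g.name}\t{g.interval[0] + 1}\t{g.interval[1]}\t{g.strand}\n")


# --- cassette GFF3 ---------------------------------------------------------

_GFF_SOURCE = "gutcrispr"


def write_cassette_gff(cassettes: list[Cassette], path: str | Path) -> None:
    """Write cassettes as GFF3: one repeat_region per cassette with
    direct_repeat and spacer children.  GFF3 is 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cas in cassettes:
            s, e = cas.interval
            attrs = (
                f"ID={cas.id};acceptance_rule={cas.acceptance_rule};"
                f"programs={','.join(sorted(cas.programs)) or '.'};"
                f"leader={cas.leader_end};complete={str(cas.complete).lower()};"
                f"cas_adjacent={str(cas.cas_adjacent).lower()};"
                f"repeat_consensus={cas.repeat_consensus}"
            )
            fh.write(
                f"{cas.contig_id}\t{_GFF_SOURCE}\trepeat_region\t{s + 1}\t{e}\t.\t.\t.\t{attrs}\n"
            )
            for k, (rs, re_) in enumerate(cas.repeat_intervals, 1):
                fh.write(
                    f"{cas.contig_id}\t{_GFF_SOURCE}\tdirect_repeat\t{rs + 1}\t{re_}\t.\t.\t.\t"
                    f"ID={cas.id}.r{k};Parent={cas.id}\n"
                )
            for sp in cas.spacers:
                ss, se = sp.interval
                fh.write(
                    f"{cas.contig_id}\t{_GFF_SOURCE}\tspacer\t{ss + 1}\t{se}\t.\t.\t.\t"
                    f"ID={cas.id}.s{sp.serial};Parent={cas.id};serial={sp.serial};"
                    f"sequence={sp.sequence}\n"
                )


def read_cassette_gff(path: str | Path) -> list[Cassette]:
    """Read cassettes written by :func:`write_cassette_gff`."""
    regions: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            contig_id, _, ftype, start, end = cols[0], cols[1], cols[2], cols[3], cols[4]
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            iv = (int(start) - 1, int(end))
            if ftype == "repeat_region":
                cid = attrs["ID"]
                order.append(cid)
                regions[cid] = {
                    "contig_id": contig_id,
                    "interval": iv,
                    "attrs": attrs,
                    "repeats": [],
                    "spacers": [],
                }
            elif ftype == "direct_repeat":
                regions[attrs["Parent"]]["repeats"].append(iv)
            elif ftype == "spacer":
                regions[attrs["Parent"]]["spacers"].append((int(attrs["serial"]), iv, attrs["sequence"]))

    cassettes = []
    for cid in order:
        r = regions[cid]
        a = r["attrs"]
        programs = frozenset(p for p in a.get("programs", "").split(",") if p and p != ".")
        spacers = [
            Spacer(cassette_id=cid, serial=serial, interval=iv, sequence=seq,
                   provisional=a.get("leader", "unknown") == "unknown")
            for serial, iv, seq in sorted(r["spacers"])
        ]
        cassettes.append(
            Cassette(
                id=cid,
                contig_id=r["contig_id"],
                interval=r["interval"],
                repeat_intervals=sorted(r["repeats"]),
                spacers=spacers,
                repeat_consensus=a.get("repeat_consensus", ""),
                programs=programs,
                acceptance_rule=a.get("acceptance_rule", "all_three"),
                cas_adjacent=a.get("cas_adjacent", "false") == "true",
                leader_end=a.get("leader", "unknown"),
                complete=a.get("complete", "false") == "true",
            )
        )
    return cassettes


# --- cohort manifests ------------------------------------------------------

def load_cohort(dataset: str) -> list[Individual]:
    """Load a bundled cohort manifest (JPN, HMP or DG) as Individual records."""
    name = dataset.lower()
    ref = resources.files("gutcrispr.data.cohorts").joinpath(f"{name}.tsv")
    individuals = []
    with ref.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            individuals.append(Individual(id=row["individual_id"], dataset=row["dataset"]))
    return individuals


def combined_cohort(datasets: tuple[str, ...] = ("HMP", "JPN", "DG")) -> list[Individual]:
    """The combined multi-dataset cohort used for cross-individual analyses."""
    out: list[Individual] = []
    seen = set()
    for ds in datasets:
        for ind in load_cohort(ds):
            if ind.id in seen:
                raise ValueError(f"duplicate individual id {ind.id} across cohorts")
            seen.add(ind.id)
            out.append(ind)
    return out
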