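"""Synthetic multi-individual gut-metagenome communities with known ground truth.

The generator emulates the data assumptions the pipeline is built for:
several individual metagenomes, each a set of assembled contigs; repeat-spacer
arrays embedded in bacterial contigs with a leader-side flank and (for a
configurable fraction) an adjacent cas locus; phage contigs of the same
individual carrying planted protospacers at controlled Hamming distance;
spacer sequences re-used across individuals; and a leader-proximal placement
bias for targeting spacers.  Background sequence is i.i.d. uniform over ACGT,
so chance full-length matches at spacer lengths >= 25 nt are negligible and
every recovered feature can be attributed to the truth manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._seq import revcomp, canonical
from .types import ArrayPrediction, Contig, GeneAnnotation, Individual, Interval

BASES = np.array(list("ACGT"))

# distance of the cas gene from the cassette's leader end, and its length
_CAS_GENE_LEN = 900
_CAS_DIST_RANGE = (50, 450)
_LEADER_BLOCK = 1500          # reserved room on the leader side (leader + cas locus)
_MARGIN = 150                 # clear background around every planted feature


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic community."""

    n_individuals: int = 12
    contigs_per_individual: int = 6
    contig_length_range: tuple[int, int] = (6000, 12000)
    n_cassettes: int = 30
    repeat_length_range: tuple[int, int] = (24, 48)
    spacer_length_range: tuple[int, int] = (25, 70)
    spacers_per_cassette_range: tuple[int, int] = (4, 12)
    n_phage_contigs: int = 2                  # per individual
    phage_length_range: tuple[int, int] = (5000, 10000)
    n_protospacers: int = 60                  # planted protospacer instances
    planted_protospacer_mismatch_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.35, 1: 0.20, 2: 0.15, 3: 0.10, 4: 0.10, 5: 0.10}
    )
    sharing_rate: float = 0.05                # fraction of spacers copied across individuals
    leader_bias: float = 0.5                  # serial weight ~ exp(-leader_bias * serial)
    cas_adjacent_fraction: float = 0.5
    n_decoys: int = 0
    seed: int = 0

    def validate(self) -> None:
        for lo, hi in (
            self.contig_length_range,
            self.repeat_length_range,
            self.spacer_length_range,
            self.spacers_per_cassette_range,
            self.phage_length_range,
        ):
            if lo > hi or lo <= 0:
                raise ValueError(f"invalid range ({lo}, {hi})")
        w = self.planted_protospacer_mismatch_distribution
        if not math.isclose(sum(w.values()), 1.0, abs_tol=1e-9):
            raise ValueError("mismatch distribution weights must sum to 1")
        if any(k < 0 or k > 6 for k in w):
            raise ValueError("mismatch weights must be over 0..6")
        max_cassette = (
            self.repeat_length_range[1] * (self.spacers_per_cassette_range[1] + 1)
            + self.spacer_length_range[1] * self.spacers_per_cassette_range[1]
        )
        if max_cassette + _LEADER_BLOCK + 2 * _MARGIN > self.contig_length_range[0]:
            raise ValueError(
                f"infeasible config: a cassette block (up to {max_cassette + _LEADER_BLOCK} nt) "
                f"may not fit in the shortest contig ({self.contig_length_range[0]} nt)"
            )
        per_ind = -(-self.n_cassettes // self.n_individuals)
        if per_ind > self.contigs_per_individual:
            raise ValueError(
                f"infeasible config: up to {per_ind} cassettes per individual but only "
                f"{self.contigs_per_individual} contigs (one cassette per contig)"
            )


@dataclass
class PlantedCassette:
    id: str
    contig_id: str
    individual_id: str
    interval: Interval
    leader_end: str                        # left | right
    repeat_intervals: list[Interval]       # plus-strand coordinates, left to right
    spacer_intervals: list[Interval]       # left to right
    spacer_serials: list[int]              # serial-from-leader of each left-to-right spacer
    spacer_sequences: list[str]            # plus-strand sequence of each left-to-right spacer
    repeat_consensus: str                  # plus-strand repeat sequence
    cas_genes: list[str] = field(default_factory=list)

    def serial_to_sequence(self) -> dict[int, str]:
        return dict(zip(self.spacer_serials, self.spacer_sequences))


@dataclass
class PlantedProtospacer:
    cassette_id: str
    serial: int                            # serial-from-leader of the source spacer
    spacer_sequence: str                   # spacer sequence (cassette plus strand)
    target_contig_id: str
    interval: Interval
    strand: str
    mismatches: int


@dataclass
class PlantedDecoy:
    contig_id: str
    interval: Interval
    unit_intervals: list[Interval]
    kind: str                              # tandem | low_complexity


@dataclass
class TruthManifest:
    cassettes: list[PlantedCassette] = field(default_factory=list)
    protospacers: list[PlantedProtospacer] = field(default_factory=list)
    shared_groups: list[dict] = field(default_factory=list)
    cas_annotations: list[GeneAnnotation] = field(default_factory=list)
    decoys: list[PlantedDecoy] = field(default_factory=list)
    occupied: dict[str, list[Interval]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cassettes": [asdict(c) for c in self.cassettes],
            "protospacers": [asdict(p) for p in self.protospacers],
            "shared_groups": self.shared_groups,
            "cas_annotations": [asdict(g) for g in self.cas_annotations],
            "decoys": [asdict(d) for d in self.decoys],
            "occupied": self.occupied,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def draw_targeting_serial(n_spacers: int, leader_bias: float,
                          rng: np.random.Generator) -> int:
    """One planted-protospacer serial: P(serial) ~ exp(-leader_bias * serial).

    leader_bias = 0 makes serials uniform over cassette positions.
    """
    w = np.exp(-leader_bias * np.arange(1, n_spacers + 1))
    return int(rng.choice(np.arange(1, n_spacers + 1), p=w / w.sum()))


def sample_targeting_flags(
    cassette_sizes: list[int],
    n_protospacers: int,
    leader_bias: float,
    rng: np.random.Generator | int,
) -> list[tuple[int, int]]:
    """Planted (cassette index, serial) pairs under the generator's placement rule.

    The community generator uses exactly this sampling when planting
    protospacers (cassette chosen uniformly, serial leader-biased); having
    it stand alone lets calibration studies draw many replicates of the
    flags without rendering contig sequences.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    out = []
    for _ in range(n_protospacers):
        c = int(rng.integers(0, len(cassette_sizes)))
        out.append((c, draw_targeting_serial(cassette_sizes[c], leader_bias, rng)))
    return out


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Substitute exactly n_mut positions with a different base."""
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


class _Reserver:
    """Non-overlapping placement of features inside one contig."""

    def __init__(self, length: int):
        self.length = length
        self.taken: list[Interval] = []

    def reserve(self, rng: np.random.Generator, size: int, margin: int = _MARGIN,
                n_tries: int = 200) -> Interval | None:
        lo, hi = margin, self.length - margin - size
        if hi < lo:
            return None
        for _ in range(n_tries):
            s = int(rng.integers(lo, hi + 1))
            iv = (s, s + size)
            if all(iv[1] + margin <= ts or iv[0] >= te + margin for ts, te in self.taken):
                self.taken.append(iv)
                return iv
        return None


def generate_community(
    config: SimulationConfig,
) -> tuple[dict[str, Contig], list[GeneAnnotation], TruthManifest]:
    """Generate contigs, cas annotations and the ground-truth manifest.

    Deterministic given ``config`` (including its seed).  Bacterial contigs
    host the cassettes; phage contigs host the planted protospacers and
    never carry cassettes, keeping protospacer space disjoint from cassette
    space.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = TruthManifest()

    individuals = [Individual(id=f"SIM{i + 1:03d}", dataset="SYN")
                   for i in range(config.n_individuals)]

    # contig skeletons and reservation state
    lengths: dict[str, int] = {}
    reservers: dict[str, _Reserver] = {}
    bacterial: dict[str, list[str]] = {ind.id: [] for ind in individuals}
    phage: dict[str, list[str]] = {ind.id: [] for ind in individuals}
    for ind in individuals:
        for k in range(config.contigs_per_individual):
            cid = f"{ind.id}.b{k + 1}"
            lengths[cid] = int(rng.integers(*config.contig_length_range, endpoint=True))
            bacterial[ind.id].append(cid)
        for k in range(config.n_phage_contigs):
            cid = f"{ind.id}.p{k + 1}"
            lengths[cid] = int(rng.integers(*config.phage_length_range, endpoint=True))
            phage[ind.id].append(cid)
    for cid, ln in lengths.items():
        reservers[cid] = _Reserver(ln)

    # --- cassette plans ----------------------------------------------------
    spacer_pool: set[str] = set()

    def fresh_spacer(length: int) -> str:
        while True:
            s = _random_seq(rng, length)
            if s not in spacer_pool and revcomp(s) not in spacer_pool:
                spacer_pool.add(s)
                return s

    owner_of: list[str] = []       # cassette index -> individual
    plans: list[dict] = []
    for c_idx in range(config.n_cassettes):
        ind = individuals[c_idx % config.n_individuals]
        n_sp = int(rng.integers(*config.spacers_per_cassette_range, endpoint=True))
        rep_len = int(rng.integers(*config.repeat_length_range, endpoint=True))
        sp_lens = [int(rng.integers(*config.spacer_length_range, endpoint=True))
                   for _ in range(n_sp)]
        plans.append({
            "id": f"cass{c_idx + 1:03d}",
            "individual": ind.id,
            "repeat": _random_seq(rng, rep_len),
            "spacers": [fresh_spacer(ln) for ln in sp_lens],   # index 0 = serial 1 (leader side)
            "leader_end": "left" if rng.random() < 0.5 else "right",
            "cas": rng.random() < config.cas_adjacent_fraction,
        })
        owner_of.append(ind.id)

    # --- cross-individual sharing -----------------------------------------
    total_spacers = sum(len(p["spacers"]) for p in plans)
    n_shared = int(round(config.sharing_rate * total_spacers))
    shared_groups: list[dict] = []
    used_recipients: set[tuple[int, int]] = set()
    if n_shared and config.n_individuals > 1:
        for _ in range(n_shared):
            for _try in range(200):
                donor_c = int(rng.integers(0, len(plans)))
                donor_s = int(rng.integers(0, len(plans[donor_c]["spacers"])))
                recip_c = int(rng.integers(0, len(plans)))
                recip_s = int(rng.integers(0, len(plans[recip_c]["spacers"])))
                if (
                    owner_of[donor_c] != owner_of[recip_c]
                    and (recip_c, recip_s) not in used_recipients
                    and (donor_c, donor_s) not in used_recipients
                ):
                    seq = plans[donor_c]["spacers"][donor_s]
                    plans[recip_c]["spacers"][recip_s] = seq
                    used_recipients.add((recip_c, recip_s))
                    shared_groups.append({
                        "sequence": canonical(seq),
                        "members": [
                            [plans[donor_c]["id"], donor_s + 1],
                            [plans[recip_c]["id"], recip_s + 1],
                        ],
                    })
                    break

    # --- place cassettes ---------------------------------------------------
    # at most one cassette per contig: distinct arrays are not observed to
    # share an assembled contig, and a lone cas locus then orients its own
    # array unambiguously
    edits: dict[str, list[tuple[int, str]]] = {cid: [] for cid in lengths}
    has_cassette: set[str] = set()
    for plan in plans:
        rep, spacers = plan["repeat"], plan["spacers"]
        array_fwd = rep + "".join(s + rep for s in spacers)   # serial 1 nearest the left end
        block = _LEADER_BLOCK + len(array_fwd)
        placed = None
        for cid in rng.permutation(bacterial[plan["individual"]]):
            if cid in has_cassette:
                continue
            iv = reservers[cid].reserve(rng, block)
            if iv is not None:
                placed = (cid, iv)
                has_cassette.add(cid)
                break
        if placed is None:
            raise ValueError(
                f"infeasible config: no room for cassette {plan['id']} "
                f"in individual {plan['individual']}"
            )
        cid, (block_s, block_e) = placed

        if plan["leader_end"] == "left":
            arr_s = block_s + _LEADER_BLOCK
            contig_array = array_fwd
        else:
            arr_s = block_s
            contig_array = revcomp(array_fwd)
        arr_e = arr_s + len(array_fwd)
        edits[cid].append((arr_s, contig_array))

        # plus-strand repeat/spacer intervals, left to right
        rep_len, n_sp = len(rep), len(spacers)
        rep_ivs, sp_ivs, serials, sp_seqs = [], [], [], []
        pos = arr_s
        for k in range(n_sp + 1):
            rep_ivs.append((pos, pos + rep_len))
            pos += rep_len
            if k < n_sp:
                # left-to-right spacer k corresponds to serial k+1 (leader left)
                # or serial n_sp-k (leader right)
                if plan["leader_end"] == "left":
                    serial, seq = k + 1, spacers[k]
                else:
                    serial, seq = n_sp - k, revcomp(spacers[n_sp - 1 - k])
                ln = len(seq)
                sp_ivs.append((pos, pos + ln))
                serials.append(serial)
                sp_seqs.append(seq)
                pos += ln
        assert pos == arr_e

        cas_names: list[str] = []
        if plan["cas"]:
            sig = rng.choice(["cas3", "cas9", "cas10", "none"], p=[0.3, 0.2, 0.2, 0.3])
            cas_names = ["cas1"] + ([] if sig == "none" else [str(sig)])
            d = int(rng.integers(*_CAS_DIST_RANGE, endpoint=True))
            if plan["leader_end"] == "left":
                g_iv = (arr_s - d - _CAS_GENE_LEN, arr_s - d)
                strand = "+"     # transcribed toward the cassette
            else:
                g_iv = (arr_e + d, arr_e + d + _CAS_GENE_LEN)
                strand = "-"
            step = _CAS_GENE_LEN // max(len(cas_names), 1)
            for gi, gname in enumerate(cas_names):
                sub = (g_iv[0] + gi * step, g_iv[0] + (gi + 1) * step)
                truth.cas_annotations.append(
                    GeneAnnotation(contig_id=cid, name=gname, interval=sub, strand=strand)
                )

        truth.cassettes.append(PlantedCassette(
            id=plan["id"],
            contig_id=cid,
            individual_id=plan["individual"],
            interval=(arr_s, arr_e),
            leader_end=plan["leader_end"],
            repeat_intervals=rep_ivs,
            spacer_intervals=sp_ivs,
            spacer_serials=serials,
            spacer_sequences=sp_seqs,
            repeat_consensus=rep if plan["leader_end"] == "left" else revcomp(rep),
            cas_genes=cas_names,
        ))

    # --- plant protospacers -------------------------------------------------
    mm_dist = config.planted_protospacer_mismatch_distribution
    mm_values = sorted(mm_dist)
    mm_weights = np.array([mm_dist[v] for v in mm_values], dtype=float)
    mm_weights /= mm_weights.sum()
    eligible = [pc for pc in truth.cassettes if phage[pc.individual_id]]
    for _ in range(config.n_protospacers):
        if not eligible:
            break
        pc = eligible[int(rng.integers(0, len(eligible)))]
        serial = draw_targeting_serial(len(pc.spacer_serials), config.leader_bias, rng)
        # spacer sequence oriented with serial 1 at the leader
        spacer_seq = pc.serial_to_sequence()[serial]
        if pc.leader_end == "right":
            spacer_seq = revcomp(spacer_seq)   # leader-frame orientation
        m = int(rng.choice(mm_values, p=mm_weights))
        proto = _mutate(rng, spacer_seq, min(m, len(spacer_seq)))
        strand = "+" if rng.random() < 0.5 else "-"
        planted = proto if strand == "+" else revcomp(proto)
        target = phage[pc.individual_id][int(rng.integers(0, len(phage[pc.individual_id])))]
        iv = reservers[target].reserve(rng, len(planted))
        if iv is None:
            continue
        edits[target].append((iv[0], planted))
        truth.protospacers.append(PlantedProtospacer(
            cassette_id=pc.id,
            serial=serial,
            spacer_sequence=spacer_seq,
            target_contig_id=target,
            interval=iv,
            strand=strand,
            mismatches=m,
        ))

    truth.shared_groups = shared_groups

    # --- render contigs ------------------------------------------------------
    contigs: dict[str, Contig] = {}
    ind_of = {cid: ind.id for ind in individuals
              for cid in bacterial[ind.id] + phage[ind.id]}
    for cid, ln in lengths.items():
        seq = list(_random_seq(rng, ln))
        for start, sub in edits[cid]:
            seq[start : start + len(sub)] = sub
        contigs[cid] = Contig(id=cid, individual_id=ind_of[cid], sequence="".join(seq))
    truth.occupied = {cid: sorted(r.taken) for cid, r in reservers.items() if r.taken}

    if config.n_decoys:
        plant_decoys(contigs, truth, config.n_decoys, rng)

    return contigs, list(truth.cas_annotations), truth


def plant_decoys(
    contigs: dict[str, Contig],
    truth: TruthManifest,
    n_decoys: int,
    rng: np.random.Generator | int,
) -> TruthManifest:
    """Plant tandem-repeat and low-complexity decoy regions as negative examples.

    Decoys imitate the periodic genomic repeats that single detectors tend to
    misreport as CRISPR arrays; they carry no cas genes and are recorded in
    the manifest so filter tests can verify their rejection.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    bacterial = [c for c in contigs.values() if ".b" in c.id]
    for d_idx in range(n_decoys):
        kind = "tandem" if d_idx % 2 == 0 else "low_complexity"
        if kind == "tandem":
            unit = _random_seq(rng, int(rng.integers(24, 41)))
        else:
            dinuc = _random_seq(rng, 2)
            unit = (dinuc * 20)[: int(rng.integers(24, 41))]
        n_units = int(rng.integers(3, 6))
        gaps = [int(rng.integers(25, 41)) for _ in range(n_units - 1)]
        pieces, unit_ivs, pos = [], [], 0
        for k in range(n_units):
            unit_ivs.append((pos, pos + len(unit)))
            pieces.append(unit)
            pos += len(unit)
            if k < n_units - 1:
                pieces.append(_random_seq(rng, gaps[k]))
                pos += gaps[k]
        region = "".join(pieces)
        placed = None
        for target in rng.permutation([c.id for c in bacterial]):
            res = truth.occupied.setdefault(target, [])
            holder = _Reserver(contigs[target].length)
            holder.taken = list(res)
            iv = holder.reserve(rng, len(region))
            if iv is not None:
                res.append(iv)
                res.sort()
                placed = (target, iv)
                break
        if placed is None:
            continue
        target, (s, _) = placed
        seq = list(contigs[target].sequence)
        seq[s : s + len(region)] = region
        contigs[target].sequence = "".join(seq)
        truth.decoys.append(PlantedDecoy(
            contig_id=target,
            interval=(s, s + len(region)),
            unit_intervals=[(s + a, s + b) for a, b in unit_ivs],
            kind=kind,
        ))
    return truth


@dataclass
class DetectorAgreement:
    """Per-program behaviour of the simulated detectors."""

    fn_rate: dict[str, float] = field(
        default_factory=lambda: {"CRT": 0.0, "CFI": 0.0, "PIL": 0.0}
    )
    boundary_jitter: int = 0
    # probability each program reports a planted decoy as an array;
    # CRT and PILER-CR pick up periodic genomic repeats, CRISPRFinder rarely does
    decoy_rate: dict[str, float] = field(
        default_factory=lambda: {"CRT": 0.8, "CFI": 0.05, "PIL": 0.6}
    )


def emit_detector_predictions(
    contigs: dict[str, Contig],
    truth: TruthManifest,
    agreement: DetectorAgreement | None = None,
    seed: int = 0,
) -> list[ArrayPrediction]:
    """Simulate CRT/CRISPRFinder/PILER-CR predictions from the truth manifest.

    Each program independently reports each planted cassette with probability
    ``1 - fn_rate`` and jitters every repeat boundary by up to
    ``boundary_jitter`` nt; planted decoys are reported per ``decoy_rate``.
    """
    agreement = agreement or DetectorAgreement()
    rng = np.random.default_rng(seed)
    preds: list[ArrayPrediction] = []
    programs = ("CRT", "CFI", "PIL")

    def jitter_intervals(ivs: list[Interval], contig_len: int) -> list[Interval]:
        j = agreement.boundary_jitter
        if j == 0:
            return list(ivs)
        out = []
        prev_end = 0
        for idx, (s, e) in enumerate(ivs):
            s2 = max(prev_end, s + int(rng.integers(-j, j + 1)))
            upper = (ivs[idx + 1][0] - 1) if idx + 1 < len(ivs) else contig_len
            e2 = min(upper, max(s2 + 1, e + int(rng.integers(-j, j + 1))))
            out.append((s2, e2))
            prev_end = e2 + 1
        return out

    for pc in truth.cassettes:
        clen = contigs[pc.contig_id].length
        for prog in programs:
            if rng.random() < agreement.fn_rate.get(prog, 0.0):
                continue
            preds.append(ArrayPrediction(
                contig_id=pc.contig_id,
                program=prog,
                array_id=f"{pc.id}.{prog}",
                repeat_intervals=jitter_intervals(pc.repeat_intervals, clen),
                repeat_consensus=pc.repeat_consensus,
            ))
    for d_idx, decoy in enumerate(truth.decoys):
        unit_seq = contigs[decoy.contig_id].sequence[slice(*decoy.unit_intervals[0])]
        for prog in programs:
            if rng.random() < agreement.decoy_rate.get(prog, 0.0):
                preds.append(ArrayPrediction(
                    contig_id=decoy.contig_id,
                    program=prog,
                    array_id=f"decoy{d_idx + 1}.{prog}",
                    repeat_intervals=list(decoy.unit_intervals),
                    repeat_consensus=unit_seq,
                ))
    return preds
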