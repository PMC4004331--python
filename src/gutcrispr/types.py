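"""Domain types for the gut-metagenome CRISPR pipeline.

Conventions
-----------
* Every interval is 0-based half-open ``(start, end)`` on the forward strand
  of its contig.  On-disk formats (GFF3, BLAST tabular, the prediction TSV)
  use their native 1-based inclusive coordinates and are converted at the
  I/O boundary, nowhere else.
* Sequences are upper-case ``{A,C,G,T,N}`` strings; ``N`` never matches.
* Spacer serial numbers are 1-based and count from the leader end once a
  cassette is oriented; until then they count from the left and are flagged
  provisional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import canonical

Interval = tuple[int, int]

DATASETS = ("JPN", "HMP", "DG", "SYN", "other")
PROGRAMS = ("CRT", "CFI", "PIL", "BUILTIN", "OTHER")
ACCEPTANCE_RULES = ("all_three", "cas_adjacent", "repeat_similar")


@dataclass(frozen=True)
class Individual:
    id: str
    dataset: str = "other"
    metadata: dict = field(default_factory=dict, compare=False)


@dataclass
class Contig:
    """A DNA sequence owned by one individual; the universal coordinate frame."""

    id: str
    individual_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    contig_id: str
    name: str          # lower-case gene label, e.g. "cas1", "cas9"
    interval: Interval
    strand: str        # "+" or "-"

    def __post_init__(self):
        s, e = self.interval
        if not 0 <= s < e:
            raise ValueError(f"bad gene interval {self.interval} for {self.name}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class ArrayPrediction:
    """One detector's view of a repeat-spacer array on a contig."""

    contig_id: str
    program: str
    repeat_intervals: list[Interval]
    repeat_consensus: str
    array_id: str = ""

    def __post_init__(self):
        ivs = self.repeat_intervals
        if len(ivs) < 2:
            raise ValueError(
                f"array {self.array_id or '?'} on {self.contig_id}: "
                f"needs >=2 repeat copies, got {len(ivs)}"
            )
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(
                    f"array {self.array_id or '?'} on {self.contig_id}: "
                    f"repeat intervals must be strictly increasing and disjoint"
                )

    @property
    def interval(self) -> Interval:
        return (self.repeat_intervals[0][0], self.repeat_intervals[-1][1])

    @property
    def spacer_intervals(self) -> list[Interval]:
        """Gaps between consecutive repeats (count = repeats - 1)."""
        ivs = self.repeat_intervals
        return [(e1, s2) for (_, e1), (s2, _) in zip(ivs, ivs[1:])]

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_intervals)


@dataclass
class Spacer:
    cassette_id: str
    serial: int                # 1-based from leader (or from left if provisional)
    interval: Interval
    sequence: str
    provisional: bool = True   # serial counted from the left, leader unknown

    @property
    def canonical_sequence(self) -> str:
        return canonical(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Cassette:
    """An accepted repeat-spacer array."""

    id: str
    contig_id: str
    interval: Interval
    repeat_intervals: list[Interval]
    spacers: list[Spacer]
    repeat_consensus: str
    programs: frozenset[str] = frozenset()
    acceptance_rule: str = "all_three"
    cas_adjacent: bool = False
    leader_end: str = "unknown"   # left | right | unknown
    complete: bool = False

    def __post_init__(self):
        s, e = self.interval
        for sp in self.spacers:
            if not (s <= sp.interval[0] < sp.interval[1] <= e):
                raise ValueError(f"spacer {sp.serial} outside cassette {self.id}")
        if self.acceptance_rule not in ACCEPTANCE_RULES:
            raise ValueError(f"unknown acceptance rule {self.acceptance_rule!r}")

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    def oriented_serials(self) -> dict[int, int]:
        """Map left-based spacer index (1..n) -> serial counted from the leader."""
        n = self.n_spacers
        if self.leader_end == "right":
            return {i: n + 1 - i for i in range(1, n + 1)}
        return {i: i for i in range(1, n + 1)}


@dataclass
class ProtospacerHit:
    """A full-spacer-length ungapped match of a spacer in a target contig."""

    spacer: Spacer
    spacer_individual: str
    target_contig_id: str
    target_interval: Interval
    strand: str
    mismatches: int
    flank_left: str = ""          # 5'->3' on the hit strand, up to 10 nt
    flank_right: str = ""
    source: str = "internal_scan"  # internal_scan | blast_extended
    passed_repeat_filter: bool = True

    @property
    def length(self) -> int:
        return self.target_interval[1] - self.target_interval[0]


@dataclass
class RepeatCluster:
    id: str
    member_cassette_ids: frozenset[str]
    params: tuple = (0.50, 0.50, 15)   # (min_identity, min_coverage, word_size)


@dataclass
class PairMatrix:
    """Individuals x individuals spacer-protospacer pair counts.

    ``counts[i, j]`` = number of reliable pairs with the protospacer in
    individual ``individuals[i]``'s metagenome and the spacer in individual
    ``individuals[j]``'s cassettes (rows = protospacer metagenomes,
    columns = spacer metagenomes).
    """

    individuals: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.individuals)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if (self.counts < 0).any():
            raise ValueError("negative pair counts")

    @property
    def total_pairs(self) -> int:
        return int(self.counts.sum())

    def to_pairs(self) -> list[tuple[str, str]]:
        """Expand to a pair list of (spacer_individual, protospacer_individual)."""
        pairs = []
        for i, proto_ind in enumerate(self.individuals):
            for j, sp_ind in enumerate(self.individuals):
                pairs.extend([(sp_ind, proto_ind)] * int(self.counts[i, j]))
        return pairs


@dataclass
class PermutationTestResult:
    observed: float
    n_perm: int
    n_as_extreme: int
    tail: str                  # lower | upper | two_sided
    seed: int
    null_mean: float
    null_sd: float

    @property
    def p_value(self) -> float:
        """Plain-fraction Monte-Carlo p-value (n_as_extreme / n_perm)."""
        return self.n_as_extreme / self.n_perm

    @property
    def p_value_plus_one(self) -> float:
        """The (k+1)/(n+1) convention, reported for reference."""
        return (self.n_as_extreme + 1) / (self.n_perm + 1)


@dataclass(frozen=True)
class TaxonHit:
    rank_index: int            # 1-based position in descending-score order
    score: float
    phylum: str = ""
    class_: str = ""
    family: str = ""
    genus: str = ""
    origin: str = "bacterial"  # bacterial | phage | plasmid
    host: str = ""             # host genus/phylum for phage/plasmid entries


@dataclass(frozen=True)
class TaxonomyLabel:
    rank: str                  # phylum | class | family | genus | domain_nonspecific | none
    name: str = ""
    reason: str = ""           # top10_phylum | top30_majority | diverse | no_hits | ...
    phylum: str = ""           # phylum context for sub-phylum calls

    def __post_init__(self):
        if self.rank in ("domain_nonspecific", "none") and self.name:
            raise ValueError("nonspecific/none labels carry no taxon name")


@dataclass(frozen=True)
class CasTypeCall:
    cassette_id: str
    type: str                  # I | II | III | unclassified
    subtype: str = ""
    evidence: tuple[str, ...] = ()
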