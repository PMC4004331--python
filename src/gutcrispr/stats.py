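"""Permutation statistics for spacer positions, spacer sharing, and
spacer-protospacer co-occurrence across individuals.

Three analyses share this module: a Monte-Carlo test for the position of
targeting/shared spacers within oriented cassettes (new spacers are added
at the leader, so targeting spacers low serial sums indicate recent
acquisition); a cassette-shuffle test for the number of spacers shared
between individuals; and a Cochran-Mantel-Haenszel statistic over
per-individual 2x2 tables of spacer-protospacer pairs, with a
protospacer-shuffle permutation null.

Monte-Carlo p-values use the plain-fraction convention k/n; the
(k+1)/(n+1) variant is available on every result object.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import numpy as np

from .types import Cassette, PairMatrix, PermutationTestResult, ProtospacerHit, Spacer

log = logging.getLogger(__name__)


# --- pair matrix ---------------------------------------------------------

def build_pair_matrix(
    hits: list[ProtospacerHit],
    individuals: list[str],
    individual_of_contig: dict[str, str],
) -> PairMatrix:
    """Count reliable spacer-protospacer pairs per (protospacer, spacer) individual.

    Rows are protospacer metagenomes, columns spacer metagenomes.  Hits
    whose spacer or target individual is not in ``individuals`` are
    excluded with a log message.
    """
    index = {ind: i for i, ind in enumerate(individuals)}
    counts = np.zeros((len(individuals), len(individuals)), dtype=np.int64)
    for h in hits:
        proto_ind = individual_of_contig.get(h.target_contig_id)
        sp_ind = h.spacer_individual
        if proto_ind not in index or sp_ind not in index:
            log.warning("hit %s -> %s: unknown individual, excluded",
                        sp_ind, h.target_contig_id)
            continue
        counts[index[proto_ind], index[sp_ind]] += 1
    return PairMatrix(individuals=list(individuals), counts=counts)


def write_pair_matrix_tsv(matrix: PairMatrix, path: str | Path) -> None:
    """Write the pair matrix in the supplementary-table layout
    (columns = spacer metagenomes, rows = protospacer metagenomes)."""
    with open(path, "w") as fh:
        fh.write("protospacer_metagenome\t" + "\t".join(matrix.individuals) + "\n")
        for i, ind in enumerate(matrix.individuals):
            fh.write(ind + "\t" + "\t".join(map(str, matrix.counts[i])) + "\n")


def read_pair_matrix_tsv(path: str | Path) -> PairMatrix:
    """Read a pair matrix written in the supplementary-table layout."""
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    columns = rows[0][1:]
    row_inds = [r[0] for r in rows[1:]]
    if row_inds != columns:
        raise ValueError("pair matrix rows and columns must list the same individuals "
                         "in the same order")
    counts = np.array([[int(x) for x in r[1:]] for r in rows[1:]], dtype=np.int64)
    return PairMatrix(individuals=columns, counts=counts)


# --- spacer classification ----------------------------------------------

def classify_spacers(
    spacers: list[Spacer],
    hits: list[ProtospacerHit],
    individual_of_cassette: dict[str, str],
    individual_of_contig: dict[str, str],
) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """Targeting and shared spacer keys ((cassette_id, serial)).

    Targeting: the spacer has at least one reliable protospacer in its own
    individual's metagenome.  Shared: the spacer's canonical sequence
    occurs in cassettes of two or more distinct individuals.
    """
    targeting: set[tuple[str, int]] = set()
    for h in hits:
        sp_ind = individual_of_cassette.get(h.spacer.cassette_id)
        if sp_ind is not None and individual_of_contig.get(h.target_contig_id) == sp_ind:
            targeting.add((h.spacer.cassette_id, h.spacer.serial))

    individuals_of_seq: dict[str, set[str]] = defaultdict(set)
    for sp in spacers:
        ind = individual_of_cassette.get(sp.cassette_id)
        if ind is not None:
            individuals_of_seq[sp.canonical_sequence].add(ind)
    shared = {
        (sp.cassette_id, sp.serial)
        for sp in spacers
        if len(individuals_of_seq[sp.canonical_sequence]) >= 2
    }
    return targeting, shared


# --- position test -------------------------------------------------------

def position_permutation_test(
    cassettes: list[Cassette],
    flagged: set[tuple[str, int]],
    *,
    tail: str = "lower",
    n_perm: int = 100_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Monte-Carlo test for the leader-proximal placement of flagged spacers.

    The statistic is the sum, over eligible cassettes, of the
    serial-from-leader of every flagged spacer; the null shuffles spacer
    positions independently within each cassette, keeping the flagged
    count per cassette fixed.  Targeting spacers concentrate near the
    leader (low serials, lower tail); shared spacers near the trailer
    (upper tail).  Only complete cassettes with a defined orientation and
    at least one flagged spacer are eligible.
    """
    n_total = len(cassettes)
    eligible: list[tuple[int, np.ndarray]] = []   # (n_spacers, flagged serials)
    n_incomplete = n_unoriented = n_unflagged = 0
    for cas in cassettes:
        if not cas.complete:
            n_incomplete += 1
            continue
        if cas.leader_end == "unknown":
            n_unoriented += 1
            continue
        serials = np.array(
            [sp.serial for sp in cas.spacers if (cas.id, sp.serial) in flagged],
            dtype=np.int64,
        )
        if serials.size == 0:
            n_unflagged += 1
            continue
        eligible.append((cas.n_spacers, serials))
    if not eligible:
        raise ValueError(
            f"no eligible cassettes for the position test: of {n_total}, "
            f"{n_incomplete} incomplete, {n_unoriented} unoriented, "
            f"{n_unflagged} without flagged spacers"
        )

    observed = float(sum(s.sum() for _, s in eligible))
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=np.int64)
    for n, serials in eligible:
        m = serials.size
        # m serials drawn without replacement from 1..n, per permutation
        draws = rng.random((n_perm, n)).argpartition(m - 1, axis=1)[:, :m] + 1
        null += draws.sum(axis=1)

    if tail == "lower":
        n_extreme = int((null <= observed).sum())
    elif tail == "upper":
        n_extreme = int((null >= observed).sum())
    else:
        raise ValueError(f"tail must be lower or upper, got {tail!r}")
    return PermutationTestResult(
        observed=observed,
        n_perm=n_perm,
        n_as_extreme=n_extreme,
        tail=tail,
        seed=seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
    )


# --- sharing test --------------------------------------------------------

def count_shared_sequences(
    assignment: np.ndarray, cassette_idx: np.ndarray, seq_codes: np.ndarray,
    n_individuals: int,
) -> int:
    """Distinct sequences present in >= 2 individuals under an assignment."""
    key = seq_codes.astype(np.int64) * n_individuals + assignment[cassette_idx]
    uniq = np.unique(key)
    seqs, counts = np.unique(uniq // n_individuals, return_counts=True)
    return int((counts >= 2).sum())


def sharing_permutation_test(
    cassette_individuals: list[str],
    cassette_spacer_sequences: list[list[str]],
    *,
    n_perm: int = 100_000,
    seed: int = 0,
    tail: str = "lower",
) -> PermutationTestResult:
    """Cassette-shuffle null for the number of shared spacer sequences.

    Cassettes are reassigned across individuals so that each individual
    keeps its cassette count (a permutation of the assignment vector); the
    statistic is the number of distinct canonical spacer sequences present
    in two or more individuals.  An observed count in the lower tail means
    individuals share fewer spacers than cassette contents would allow at
    random.
    """
    individuals = sorted(set(cassette_individuals))
    if len(individuals) < 2:
        raise ValueError("sharing test needs cassettes from >=2 individuals")
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    assignment = np.array([ind_index[i] for i in cassette_individuals], dtype=np.int64)

    seq_index: dict[str, int] = {}
    cassette_idx, seq_codes = [], []
    for ci, seqs in enumerate(cassette_spacer_sequences):
        for s in seqs:
            cassette_idx.append(ci)
            seq_codes.append(seq_index.setdefault(s, len(seq_index)))
    cassette_idx = np.array(cassette_idx, dtype=np.int64)
    seq_codes = np.array(seq_codes, dtype=np.int64)
    n_ind = len(individuals)

    observed = count_shared_sequences(assignment, cassette_idx, seq_codes, n_ind)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        perm = rng.permutation(assignment)
        null[b] = count_shared_sequences(perm, cassette_idx, seq_codes, n_ind)

    if tail == "lower":
        n_extreme = int((null <= observed).sum())
    elif tail == "upper":
        n_extreme = int((null >= observed).sum())
    else:
        raise ValueError(f"tail must be lower or upper, got {tail!r}")
    return PermutationTestResult(
        observed=float(observed),
        n_perm=n_perm,
        n_as_extreme=n_extreme,
        tail=tail,
        seed=seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
    )


# --- Cochran-Mantel-Haenszel ---------------------------------------------

def _cmh_terms(pairs_spacer: np.ndarray, pairs_proto: np.ndarray,
               individuals: np.ndarray) -> tuple[float, float, float]:
    """(sum a_k, sum E_k, sum Var_k) over non-degenerate individual strata."""
    n = pairs_spacer.size
    sum_a = sum_e = sum_v = 0.0
    for k in individuals:
        r1 = int((pairs_spacer == k).sum())
        c1 = int((pairs_proto == k).sum())
        if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
            continue    # degenerate stratum: zero margin, contributes nothing
        a = int(((pairs_spacer == k) & (pairs_proto == k)).sum())
        r2, c2 = n - r1, n - c1
        sum_a += a
        sum_e += r1 * c1 / n
        sum_v += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    return sum_a, sum_e, sum_v


def cmh_statistic(
    pairs: list[tuple[str, str]] | PairMatrix,
    *,
    continuity_correction: bool = False,
) -> float:
    """Cochran-Mantel-Haenszel chi-square over per-individual 2x2 strata.

    Each individual k defines a stratum classifying every
    spacer-protospacer pair by (spacer from k?) x (protospacer from k?).
    Pairs (not unique spacers) are the sampling unit.
    """
    if isinstance(pairs, PairMatrix):
        pair_list = pairs.to_pairs()
        individuals = pairs.individuals
    else:
        pair_list = pairs
        individuals = sorted({i for p in pair_list for i in p})
    if not pair_list:
        raise ValueError("no pairs: CMH undefined")
    sp = np.array([p[0] for p in pair_list])
    pr = np.array([p[1] for p in pair_list])
    sum_a, sum_e, sum_v = _cmh_terms(sp, pr, np.array(individuals))
    if sum_v == 0:
        raise ValueError("all strata degenerate: CMH undefined")
    num = abs(sum_a - sum_e)
    if continuity_correction:
        num = max(num - 0.5, 0.0)
    return num * num / sum_v


def cmh_permutation_test(
    pairs: list[tuple[str, str]] | PairMatrix,
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    continuity_correction: bool = False,
) -> PermutationTestResult:
    """Protospacer-shuffle null for the CMH statistic.

    The multiset of protospacer-individual labels is permuted over pairs
    (spacer labels fixed), preserving each individual's protospacer count;
    upper-tail p = fraction of permuted CMH >= observed.

    Under this permutation every stratum's margins (spacer and protospacer
    counts) are invariant, so only the summed diagonal count changes; the
    permuted statistic is recomputed from that count against the fixed
    expectation and variance terms.
    """
    if isinstance(pairs, PairMatrix):
        pair_list = pairs.to_pairs()
        individuals = pairs.individuals
    else:
        pair_list = pairs
        individuals = sorted({i for p in pair_list for i in p})
    if not pair_list:
        raise ValueError("no pairs: CMH undefined")
    sp = np.array([p[0] for p in pair_list])
    pr = np.array([p[1] for p in pair_list])
    _, sum_e, sum_v = _cmh_terms(sp, pr, np.array(individuals))
    if sum_v == 0:
        raise ValueError("all strata degenerate: CMH undefined")

    def stat(sum_a: float) -> float:
        num = abs(sum_a - sum_e)
        if continuity_correction:
            num = max(num - 0.5, 0.0)
        return num * num / sum_v

    observed = stat(float((sp == pr).sum()))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    pr_codes = pr.copy()
    for b in range(n_perm):
        null[b] = stat(float((sp == rng.permutation(pr_codes)).sum()))
    n_extreme = int((null >= observed).sum())
    return PermutationTestResult(
        observed=observed,
        n_perm=n_perm,
        n_as_extreme=n_extreme,
        tail="upper",
        seed=seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
    )


def majority_foreign_count(matrix: PairMatrix) -> dict:
    """Individuals whose spacers find most of their protospacers elsewhere.

    Over individuals j whose spacers have at least one protospacer pair
    (column sum >= 1), count those where foreign pairs (rows i != j)
    strictly outnumber same-individual pairs.  Fractions are reported both
    over the eligible individuals and over the whole cohort.
    """
    col_sums = matrix.counts.sum(axis=0)
    diag = np.diag(matrix.counts)
    eligible = col_sums >= 1
    foreign_major = eligible & (col_sums - diag > diag)
    n_eligible = int(eligible.sum())
    count = int(foreign_major.sum())
    return {
        "count": count,
        "n_with_pairs": n_eligible,
        "fraction_of_with_pairs": count / n_eligible if n_eligible else float("nan"),
        "n_individuals": len(matrix.individuals),
        "fraction_of_all": count / len(matrix.individuals) if matrix.individuals else float("nan"),
    }
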