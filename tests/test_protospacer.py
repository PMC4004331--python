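"""Protospacer scanning, BLAST extension, contamination filters, PAM."""

import numpy as np

from gutcrispr._seq import revcomp
from gutcrispr.io import BlastHit
from gutcrispr.protospacer import (
    contamination_budget,
    extend_blast_hit,
    extract_pam_flanks,
    make_pseudospacers,
    pam_scan,
    pseudo_flank_filter,
    repeat_contamination_filter,
    scan_targets,
)
from gutcrispr.types import Contig, Spacer

from conftest import random_seq


def _spacer(seq, cid="k1", serial=1):
    return Spacer(cassette_id=cid, serial=serial, interval=(0, len(seq)), sequence=seq)


def brute_force_scan(spacer_seq, target_seq, excluded, max_mm):
    """Independent quadruple-loop oracle for the corpus matcher."""
    L = len(spacer_seq)
    out = set()
    for strand, q in (("+", spacer_seq), ("-", revcomp(spacer_seq))):
        for pos in range(len(target_seq) - L + 1):
            if any(pos < e and s < pos + L for s, e in excluded):
                continue
            mm = 0
            for a, b in zip(q, target_seq[pos : pos + L]):
                if a != b or a == "N" or b == "N":
                    mm += 1
            if mm <= max_mm:
                out.add((pos, strand, mm))
    return out


def _mutate(rng, seq, k):
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = [b for b in "ACGT" if b != out[p]][rng.integers(0, 3)]
    return "".join(out)


def test_scan_matches_brute_force_oracle_on_planted_instances():
    rng = np.random.default_rng(51)
    for case in range(60):
        L = int(rng.integers(25, 41))
        spacer_seq = random_seq(rng, L)
        target = random_seq(rng, 400)
        # plant a copy at a controlled distance, sometimes reverse complemented
        k = int(rng.integers(0, 7))
        planted = _mutate(rng, spacer_seq, k)
        if rng.random() < 0.5:
            planted = revcomp(planted)
        at = int(rng.integers(0, 400 - L))
        target = target[:at] + planted + target[at + L:]
        excluded = [(100, 160)] if rng.random() < 0.3 else []
        contig = {"t": Contig(id="t", individual_id="i", sequence=target)}
        hits = scan_targets([_spacer(spacer_seq)], contig, {"t": excluded})
        got = {(h.target_interval[0], h.strand, h.mismatches) for h in hits}
        assert got == brute_force_scan(spacer_seq, target, excluded, 4), f"case {case}"


def test_threshold_boundary_four_in_five_out():
    rng = np.random.default_rng(52)
    spacer_seq = random_seq(rng, 30)
    bg = random_seq(rng, 500)
    t4 = bg[:100] + _mutate(rng, spacer_seq, 4) + bg[130:]
    t5 = bg[:100] + _mutate(rng, spacer_seq, 5) + bg[130:]
    contigs = {
        "h4": Contig(id="h4", individual_id="i", sequence=t4),
        "h5": Contig(id="h5", individual_id="i", sequence=t5),
    }
    hits = scan_targets([_spacer(spacer_seq)], contigs, {})
    assert {(h.target_contig_id, h.mismatches) for h in hits} == {("h4", 4)}


def test_own_cassette_locus_excluded():
    rng = np.random.default_rng(53)
    spacer_seq = random_seq(rng, 30)
    bg = random_seq(rng, 600)
    seq = bg[:200] + spacer_seq + bg[230:]          # spacer inside its cassette
    contigs = {"src": Contig(id="src", individual_id="i", sequence=seq)}
    hits = scan_targets([_spacer(spacer_seq)], contigs, {"src": [(150, 300)]})
    assert hits == []


def test_spacer_with_n_counts_n_as_mismatch():
    rng = np.random.default_rng(54)
    core = random_seq(rng, 30)
    spacer_seq = "N" * 4 + core[4:]
    target = random_seq(rng, 100) + core + random_seq(rng, 100)
    contigs = {"t": Contig(id="t", individual_id="i", sequence=target)}
    hits = scan_targets([_spacer(spacer_seq)], contigs, {})
    assert [h.mismatches for h in hits] == [4]
    spacer5n = "N" * 5 + core[5:]
    assert scan_targets([_spacer(spacer5n)], contigs, {}) == []


def test_flanks_are_read_on_hit_strand():
    rng = np.random.default_rng(55)
    spacer_seq = random_seq(rng, 30)
    left, right = random_seq(rng, 10), random_seq(rng, 10)
    pad = random_seq(rng, 50)
    target = pad + left + revcomp(spacer_seq) + right + pad
    contigs = {"t": Contig(id="t", individual_id="i", sequence=target)}
    (hit,) = scan_targets([_spacer(spacer_seq)], contigs, {})
    assert hit.strand == "-"
    # on the minus strand the 5' flank is the revcomp of the plus-strand right flank
    assert hit.flank_left == revcomp(right)
    assert hit.flank_right == revcomp(left)


# --- BLAST extension ------------------------------------------------------

def _raw_hit(qs, qe, ss, se, gaps=0):
    strand = "+" if ss <= se else "-"
    iv = (ss - 1, se) if strand == "+" else (se - 1, ss)
    return BlastHit(query_id="sp", subject_id="t", pct_identity=95.0,
                    align_length=qe - qs + 1, mismatches=0, gap_opens=gaps,
                    query_start=qs, query_end=qe, subject_interval=iv,
                    strand=strand, evalue=1e-9, bitscore=50.0)


def test_extension_recovers_terminal_mismatches():
    rng = np.random.default_rng(56)
    spacer_seq = random_seq(rng, 30)
    bg = random_seq(rng, 300)
    # plant a copy whose first two bases differ: BLAST-like hit covers 3..30
    planted = _mutate(rng, spacer_seq[:2], 2) + spacer_seq[2:]
    target = Contig(id="t", individual_id="i", sequence=bg[:100] + planted + bg[130:])
    raw = _raw_hit(3, 30, 103, 130)
    hit = extend_blast_hit(raw, _spacer(spacer_seq), target)
    assert hit is not None
    assert hit.target_interval == (100, 130)
    assert hit.mismatches == 2
    assert hit.source == "blast_extended"


def test_extension_identity_flanks_keep_mismatch_count():
    rng = np.random.default_rng(57)
    spacer_seq = random_seq(rng, 30)
    bg = random_seq(rng, 300)
    target = Contig(id="t", individual_id="i", sequence=bg[:100] + spacer_seq + bg[130:])
    raw = _raw_hit(3, 30, 103, 130)   # aligned region misses identical positions 1-2
    hit = extend_blast_hit(raw, _spacer(spacer_seq), target)
    assert hit.mismatches == 0


def test_extension_past_contig_end_rejected():
    rng = np.random.default_rng(58)
    spacer_seq = random_seq(rng, 30)
    target = Contig(id="t", individual_id="i",
                    sequence=spacer_seq[2:] + random_seq(rng, 100))
    raw = _raw_hit(3, 30, 1, 28)      # needs 2 nt left of the contig start
    assert extend_blast_hit(raw, _spacer(spacer_seq), target) is None


def test_gapped_hit_rejected():
    rng = np.random.default_rng(59)
    spacer_seq = random_seq(rng, 30)
    target = Contig(id="t", individual_id="i", sequence=random_seq(rng, 200))
    assert extend_blast_hit(_raw_hit(1, 30, 50, 79, gaps=1),
                            _spacer(spacer_seq), target) is None


def test_minus_strand_extension_mismatch_recount():
    rng = np.random.default_rng(60)
    spacer_seq = random_seq(rng, 30)
    bg = random_seq(rng, 300)
    planted = revcomp(spacer_seq)
    target = Contig(id="t", individual_id="i", sequence=bg[:100] + planted + bg[130:])
    # minus-strand raw hit covering spacer 1..28 (subject plus-strand 103..130)
    raw = _raw_hit(1, 28, 130, 103)
    hit = extend_blast_hit(raw, _spacer(spacer_seq), target)
    assert hit is not None
    assert hit.target_interval == (100, 130)
    assert hit.strand == "-"
    assert hit.mismatches == 0


def test_extension_mismatch_counts_match_oracle_on_random_cases():
    rng = np.random.default_rng(61)
    for _ in range(200):
        L = int(rng.integers(25, 41))
        spacer_seq = random_seq(rng, L)
        planted = _mutate(rng, spacer_seq, int(rng.integers(0, 5)))
        minus = rng.random() < 0.5
        insert = revcomp(planted) if minus else planted
        at = int(rng.integers(20, 60))
        seq = random_seq(rng, at) + insert + random_seq(rng, 60)
        target = Contig(id="t", individual_id="i", sequence=seq)
        qs = int(rng.integers(1, 6))
        qe = int(rng.integers(L - 4, L + 1))
        if minus:
            raw = _raw_hit(qs, qe, at + (L - qs + 1), at + (L - qe) + 1)
        else:
            raw = _raw_hit(qs, qe, at + qs, at + qe)
        hit = extend_blast_hit(raw, _spacer(spacer_seq), target, max_mismatches=L)
        window = seq[at : at + L]
        if minus:
            window = revcomp(window)
        expected = sum(a != b for a, b in zip(spacer_seq, window))
        assert hit is not None and hit.mismatches == expected


# --- contamination filters -----------------------------------------------

def test_repeat_filter_catches_undetected_cassette_copy():
    rng = np.random.default_rng(62)
    rep = random_seq(rng, 32)
    spacer_seq = random_seq(rng, 35)
    bg = random_seq(rng, 2000)
    # target carries an unannotated repeat-spacer-repeat copy
    hidden = rep + spacer_seq + rep
    contaminated = bg[:500] + hidden + bg[500 + len(hidden):]
    clean = random_seq(rng, 600) + spacer_seq + random_seq(rng, 600)
    contigs = {
        "bad": Contig(id="bad", individual_id="i", sequence=contaminated),
        "good": Contig(id="good", individual_id="i", sequence=clean),
    }
    hits = scan_targets([_spacer(spacer_seq)], contigs, {})
    assert {h.target_contig_id for h in hits} == {"bad", "good"}
    repeat_contamination_filter(hits, {"k1": rep}, contigs)
    status = {h.target_contig_id: h.passed_repeat_filter for h in hits}
    assert status == {"bad": False, "good": True}


def test_repeat_filter_budget_scales_with_length():
    assert contamination_budget(27) == 5   # ~4/27 spacer ratio
    assert contamination_budget(40) == 6


# --- pseudospacers --------------------------------------------------------

def _pseudo_setup(rng, cassette_margin=4000):
    contig_len = 10000
    bg = random_seq(rng, contig_len)
    spacer_seq = bg[4300:4332]
    spacer = Spacer(cassette_id="k1", serial=1, interval=(4300, 4332),
                    sequence=spacer_seq)
    contigs = {
        "host": Contig(id="host", individual_id="A", sequence=bg),
        "free": Contig(id="free", individual_id="A", sequence=random_seq(rng, 5000)),
    }
    intervals = {"host": [(cassette_margin, 5000)]}
    return spacer, contigs, intervals


def test_pseudospacer_avoids_cassette_and_is_deterministic():
    rng = np.random.default_rng(63)
    spacer, contigs, intervals = _pseudo_setup(rng)
    args = ([spacer], contigs, intervals, {"k1": "host"},
            {"host": "A", "free": "A"})
    ps1 = make_pseudospacers(*args, seed=7)
    ps2 = make_pseudospacers(*args, seed=7)
    assert len(ps1) == 1
    p = ps1[0]
    assert p.rule == "same_contig"
    assert p.interval[1] - p.interval[0] == 32
    s, e = p.interval
    assert e <= 4000 or s >= 5000
    assert (ps1[0].contig_id, ps1[0].interval) == (ps2[0].contig_id, ps2[0].interval)


def test_pseudospacer_fallback_when_flanks_short():
    rng = np.random.default_rng(64)
    spacer, contigs, _ = _pseudo_setup(rng)
    # cassette covers all but <100 nt on each side
    intervals = {"host": [(50, 9950)]}
    ps = make_pseudospacers([spacer], contigs, intervals, {"k1": "host"},
                            {"host": "A", "free": "A"}, seed=7)
    assert ps[0].rule == "fallback_contig"
    assert ps[0].contig_id == "free"


def test_pseudospacer_skipped_without_cassette_free_contig():
    rng = np.random.default_rng(65)
    spacer, contigs, _ = _pseudo_setup(rng)
    del contigs["free"]
    intervals = {"host": [(50, 9950)]}
    ps = make_pseudospacers([spacer], contigs, intervals, {"k1": "host"},
                            {"host": "A"}, seed=7)
    assert ps == []


def test_pseudo_flank_filter_drops_homology_context():
    rng = np.random.default_rng(66)
    rep_len = 30
    # a "conserved gene" copied into both the source and the target contig
    gene = random_seq(rng, 200)
    src_bg = random_seq(rng, 2000)
    src = src_bg[:800] + gene + src_bg[1000:]
    tgt_bg = random_seq(rng, 2000)
    tgt = tgt_bg[:500] + gene + tgt_bg[700:]
    contigs = {
        "src": Contig(id="src", individual_id="A", sequence=src),
        "tgt": Contig(id="tgt", individual_id="B", sequence=tgt),
    }
    # pseudospacer drawn inside the conserved gene on src
    orig = Spacer(cassette_id="k1", serial=1, interval=(0, 32), sequence="A" * 32)
    from gutcrispr.protospacer import Pseudospacer
    ps = Pseudospacer(original=orig, contig_id="src", interval=(860, 892),
                      sequence=src[860:892], rule="same_contig")
    pseudo_sp = ps.as_spacer()
    hits = scan_targets([pseudo_sp], contigs, {})
    hits = [h for h in hits if h.target_contig_id == "tgt"]
    assert hits, "pseudospacer should match the conserved gene in the target"
    surviving = pseudo_flank_filter(hits, [ps], {"k1": "G" * rep_len}, contigs)
    assert surviving == []


def test_pseudo_flank_filter_keeps_clean_pairs():
    rng = np.random.default_rng(67)
    frag = random_seq(rng, 32)
    src = random_seq(rng, 900) + frag + random_seq(rng, 900)
    tgt = random_seq(rng, 500) + frag + random_seq(rng, 500)
    contigs = {
        "src": Contig(id="src", individual_id="A", sequence=src),
        "tgt": Contig(id="tgt", individual_id="B", sequence=tgt),
    }
    orig = Spacer(cassette_id="k1", serial=1, interval=(0, 32), sequence="A" * 32)
    from gutcrispr.protospacer import Pseudospacer
    ps = Pseudospacer(original=orig, contig_id="src", interval=(900, 932),
                      sequence=frag, rule="same_contig")
    hits = [h for h in scan_targets([ps.as_spacer()], contigs, {})
            if h.target_contig_id == "tgt"]
    surviving = pseudo_flank_filter(hits, [ps], {"k1": "G" * 30}, contigs)
    assert len(surviving) == len(hits) > 0
    assert pseudo_flank_filter([], [ps], {"k1": "G" * 30}, contigs) == []


# --- PAM ------------------------------------------------------------------

def _hit_with_flanks(left, right, cid="k1"):
    sp = Spacer(cassette_id=cid, serial=1, interval=(0, 30), sequence="A" * 30)
    from gutcrispr.types import ProtospacerHit
    return ProtospacerHit(spacer=sp, spacer_individual="A", target_contig_id="t",
                          target_interval=(0, 30), strand="+", mismatches=0,
                          flank_left=left, flank_right=right)


def test_pam_perfectly_conserved_motif_reported():
    rng = np.random.default_rng(68)
    hits = [_hit_with_flanks(random_seq(rng, 7) + "TTC", random_seq(rng, 10))
            for _ in range(10)]
    table = extract_pam_flanks(hits, {"k1": "RC001"})
    report = pam_scan(table)
    left = report["RC001"]["left"]
    assert left["motif"] == "TTC"
    assert all(ic >= 1.5 for ic in left["ic"][-3:])
    assert report["RC001"]["right"]["motif"] is None
    # without the small-sample correction the conserved columns carry 2 bits
    raw = pam_scan(table, small_sample_correction=False)
    assert all(ic == 2.0 for ic in raw["RC001"]["left"]["ic"][-3:])


def test_pam_uniform_flanks_yield_no_motif():
    rng = np.random.default_rng(69)
    hits = [_hit_with_flanks(random_seq(rng, 10), random_seq(rng, 10))
            for _ in range(20)]
    report = pam_scan(extract_pam_flanks(hits, {"k1": "RC001"}))
    assert report["RC001"]["left"]["motif"] is None
    assert report["RC001"]["right"]["motif"] is None


def test_pam_small_groups_skipped():
    rng = np.random.default_rng(70)
    hits = [_hit_with_flanks("TTCTTCTTCA", random_seq(rng, 10)) for _ in range(2)]
    report = pam_scan(extract_pam_flanks(hits, {"k1": "RC001"}))
    assert report["RC001"]["left"]["reason"] == "too_few_hits"
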