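import numpy as np
import pytest

from rddaudit import align
from rddaudit.align import (
    ConfigurationError,
    CoordinateError,
    FlankDatabase,
    FlankEntry,
    ReadAlignment,
    SitePileup,
    build_flank_db,
    filter_genomic_alignments,
    flank_site_map,
    map_reads,
    pileup,
    read_external_alignments,
    write_sam,
)
from rddaudit.io import RddSite

# ---------------------------------------------------------------------------
# independent oracle helpers (string-based, no package internals)
# ---------------------------------------------------------------------------

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def dist(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def brute_map(read: str, targets: dict[str, str], max_mm: int):
    """Exhaustive scan with the documented tie policy; None if unmapped/ambiguous."""
    placements = []
    for strand, seq in (("+", read), ("-", rc(read))):
        for tid, tseq in targets.items():
            for start in range(len(tseq) - len(seq) + 1):
                d = dist(seq, tseq[start : start + len(seq)])
                if d <= max_mm:
                    placements.append((d, tid, start, strand))
    if not placements:
        return None
    best = min(p[0] for p in placements)
    bests = [p for p in placements if p[0] == best]
    if len({p[1] for p in bests}) > 1:
        return None
    bests.sort(key=lambda p: (p[2], p[3]))
    return bests[0]


def random_instance(rng, with_n=False):
    n_targets = int(rng.integers(1, 4))
    targets = {
        f"t{i}": "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 200))))
        for i in range(n_targets)
    }
    max_mm = int(rng.integers(0, 6))
    read_len = int(rng.integers(12, 41))
    reads = []
    for j in range(8):
        kind = rng.integers(0, 4)
        tid = f"t{int(rng.integers(n_targets))}"
        tseq = targets[tid]
        start = int(rng.integers(0, len(tseq) - read_len + 1))
        seq = list(tseq[start : start + read_len])
        if kind == 1:  # mutate a few bases
            for _ in range(int(rng.integers(0, max_mm + 3))):
                p = int(rng.integers(read_len))
                seq[p] = rng.choice(list("ACGT"))
        elif kind == 2:  # reverse-complement
            seq = list(rc("".join(seq)))
        elif kind == 3:  # unrelated
            seq = list(rng.choice(list("ACGT"), size=read_len))
        if with_n and rng.random() < 0.3:
            seq[int(rng.integers(read_len))] = "N"
        reads.append((f"r{j}", "".join(seq)))
    return reads, targets, max_mm


def assert_matches_oracle(reads, targets, max_mm):
    got = {a.read_id: a for a in map_reads(reads, targets, max_mm)}
    for rid, seq in reads:
        expect = brute_map(seq, targets, max_mm)
        if expect is None:
            assert rid not in got, f"{rid}: oracle says unmapped/ambiguous, got {got.get(rid)}"
        else:
            d, tid, start, strand = expect
            a = got[rid]
            assert (a.n_mismatches, a.target, a.target_start, a.strand) == (d, tid, start, strand)
            assert len(a.mismatch_positions) == a.n_mismatches


# ---------------------------------------------------------------------------
# flank database
# ---------------------------------------------------------------------------

def test_flank_extraction_plus_strand():
    sites = [RddSite("s1", "chr1", 4, "+", "G", "A")]
    res = build_flank_db(sites, {"chr1": "AACGTAA"}, flank=2)
    (entry,) = res.database.entries
    assert entry.seq == "ACGTA"
    assert entry.rdd_offset == 2
    assert entry.seq[entry.rdd_offset] == "G"


def test_flank_extraction_minus_strand():
    # oracle: independent reverse complement of the extracted window
    sites = [RddSite("s1", "chr1", 4, "-", "C", "A")]
    res = build_flank_db(sites, {"chr1": "AACGTAA"}, flank=2)
    (entry,) = res.database.entries
    assert entry.seq == rc("ACGTA") == "TACGT"
    assert entry.rdd_offset == 2
    assert entry.seq[2] == "C"


def test_reference_mismatch_routing():
    # reference already shows the claimed RNA nucleotide
    sites = [RddSite("s1", "chr1", 4, "+", "A", "G")]  # ref base is G = B
    res = build_flank_db(sites, {"chr1": "AACGTAA"}, flank=2)
    assert res.reference_mismatch == ["s1"]
    assert len(res.database) == 0


def test_inconsistent_site_excluded():
    sites = [RddSite("s1", "chr1", 4, "+", "C", "T")]  # ref base G, neither A nor B
    res = build_flank_db(sites, {"chr1": "AACGTAA"}, flank=2)
    assert res.inconsistent == ["s1"]
    assert len(res.database) == 0 and res.reference_mismatch == []


def test_truncated_flank_near_contig_end():
    sites = [RddSite("s1", "chr1", 2, "+", "A", "G")]
    res = build_flank_db(sites, {"chr1": "AACGTAA"}, flank=5)
    (entry,) = res.database.entries
    assert entry.seq == "AACGTAA"
    assert entry.rdd_offset == 1


def test_coordinate_error():
    with pytest.raises(CoordinateError):
        build_flank_db([RddSite("s1", "chr1", 99, "+", "A", "G")], {"chr1": "ACGT"})
    with pytest.raises(CoordinateError):
        build_flank_db([RddSite("s1", "chrX", 1, "+", "A", "G")], {"chr1": "ACGT"})


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def test_exact_substring_maps_with_zero_mismatches(rng):
    t = "".join(rng.choice(list("ACGT"), size=300))
    reads = [("r0", t[40:90])]
    (a,) = map_reads(reads, {"t": t}, 2)
    assert (a.target, a.target_start, a.n_mismatches, a.strand) == ("t", 40, 0, "+")


def test_threshold_exclusivity(rng):
    t = "".join(rng.choice(list("ACGT"), size=120))
    seq = list(t[10:60])
    # plant exactly max_mm+1 mismatches at distinct positions
    for p in (3, 17, 31):
        seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
    assert map_reads([("r", "".join(seq))], {"t": t}, 2) == []


def test_empty_targets_raise():
    with pytest.raises(ConfigurationError):
        map_reads([("r", "ACGT")], {}, 1)


def test_read_longer_than_target_unmapped():
    assert map_reads([("r", "ACGTACGTA")], {"t": "ACGT"}, 3) == []


def test_map_reads_vs_bruteforce_oracle(rng):
    for i in range(60):
        reads, targets, max_mm = random_instance(rng, with_n=(i % 3 == 0))
        assert_matches_oracle(reads, targets, max_mm)


def test_strand_involution(rng):
    for _ in range(20):
        reads, targets, max_mm = random_instance(rng)
        fwd = {a.read_id: a for a in map_reads(reads, targets, max_mm)}
        rev = {a.read_id: a for a in map_reads([(i, rc(s)) for i, s in reads], targets, max_mm)}
        for rid in fwd:
            if rid in rev and fwd[rid].target == rev[rid].target:
                assert fwd[rid].n_mismatches == rev[rid].n_mismatches
                if fwd[rid].target_start == rev[rid].target_start:
                    assert fwd[rid].strand != rev[rid].strand


def test_ambiguous_read_discarded():
    t1 = "AAAACCCCGGGGTTTTACGT"
    targets = {"a": t1 + "AC", "b": "GG" + t1}
    assert map_reads([("r", t1)], targets, 0) == []


def test_tie_within_target_leftmost():
    t = "ACGTACGTACGT"
    (a,) = map_reads([("r", "ACGT")], {"t": t}, 0)
    assert a.target_start == 0


# ---------------------------------------------------------------------------
# genomic-alignment filter
# ---------------------------------------------------------------------------

def _db_one(seq="ACGTACGTAC", off=4):
    return FlankDatabase([FlankEntry("s1", seq, off, "+", "chr1", 0)], flank=4)


def _aln(positions, covers=True):
    return ReadAlignment(
        read_id="r", target="s1", target_start=0, strand="+",
        n_mismatches=len(positions), mismatch_positions=tuple(positions),
        aligned_seq="ACGTACGTAC", covers_rdd=covers,
    )


def test_filter_allows_one_nonrdd_plus_rdd_mismatch():
    db = _db_one()
    kept = filter_genomic_alignments([_aln([4, 7])], db)  # RDD offset 4 + one other
    assert len(kept) == 1


def test_filter_eliminates_three_nonrdd_mismatches():
    assert filter_genomic_alignments([_aln([1, 2, 3])], _db_one()) == []


def test_filter_keeps_single_rdd_mismatch():
    assert len(filter_genomic_alignments([_aln([4])], _db_one())) == 1


def test_filter_never_increases_and_is_idempotent(rng):
    db = _db_one()
    alns = [_aln(sorted(rng.choice(10, size=int(rng.integers(0, 4)), replace=False)))
            for _ in range(50)]
    once = filter_genomic_alignments(alns, db)
    assert len(once) <= len(alns)
    assert filter_genomic_alignments(once, db) == once


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def test_pileup_counts_simple():
    db = _db_one()
    alns = []
    for i in range(7):
        alns.append(ReadAlignment(f"a{i}", "s1", 0, "+", 0, (), "ACGTACGTAC", True, "A", "i1"))
    for i in range(3):
        alns.append(ReadAlignment(f"g{i}", "s1", 0, "+", 1, (4,), "ACGTGCGTAC", True, "G", "i1"))
    piles = pileup(alns, flank_site_map(db), "DNA")
    p = piles[("s1", "i1")]
    assert p.abo("A", "G") == (7, 3, 0)


def test_pileup_empty_when_site_uncovered():
    db = _db_one(off=9)
    aln = ReadAlignment("r", "s1", 0, "+", 0, (), "ACGT", individual="i1")
    assert pileup([aln], flank_site_map(db), "DNA") == {}


def test_pileup_max_mismatch_filter():
    db = _db_one()
    a = ReadAlignment("r", "s1", 0, "+", 3, (1, 2, 3), "ACGTACGTAC", True, "A", "i1")
    assert pileup([a], flank_site_map(db), "RNA", max_mismatches=2) == {}
    assert len(pileup([a], flank_site_map(db), "RNA", max_mismatches=3)) == 1


def test_pileup_matches_column_tally_oracle(rng):
    """Pileup totals equal an independent per-column tally over the alignments."""
    target = "".join(rng.choice(list("ACGT"), size=80))
    targets = {"t": target}
    site_cols = {"t": [("sA", 25), ("sB", 60)]}
    reads = []
    for j in range(200):
        start = int(rng.integers(0, 51))
        seq = list(target[start : start + 30])
        for _ in range(int(rng.integers(0, 3))):
            seq[int(rng.integers(30))] = rng.choice(list("ACGT"))
        reads.append((f"r{j}", "".join(seq)))
    alns = map_reads(reads, targets, 4, individual="i1")
    piles = pileup(alns, site_cols, "RNA")
    # oracle: tally aligned bases per column directly
    for sid, col in site_cols["t"]:
        expect: dict[str, int] = {}
        for a in alns:
            if a.target_start <= col < a.target_start + 30:
                b = a.aligned_seq[col - a.target_start]
                expect[b] = expect.get(b, 0) + 1
        got = piles.get((sid, "i1"))
        assert (got.counts if got else {}) == expect


# ---------------------------------------------------------------------------
# SAM interchange
# ---------------------------------------------------------------------------

def test_sam_roundtrip_pileups(tmp_path, rng):
    target = "".join(rng.choice(list("ACGT"), size=99))
    db = FlankDatabase([FlankEntry("s1", target, 49, "+", "chr1", 100)], flank=49)
    reads = []
    for j in range(60):
        start = int(rng.integers(0, 50))
        seq = list(target[start : start + 50])
        if rng.random() < 0.5:
            seq[int(rng.integers(50))] = rng.choice(list("ACGT"))
        if rng.random() < 0.5:
            seq = list(rc("".join(seq)))
        reads.append((f"r{j}", "".join(seq)))
    alns = map_reads(reads, db, 5, individual="i1")
    assert alns
    sam = tmp_path / "out.sam"
    write_sam(alns, db, sam)
    back = read_external_alignments(sam, db)
    p1 = pileup(alns, flank_site_map(db), "DNA")
    p2 = pileup(back, flank_site_map(db), "DNA")
    assert {k: v.counts for k, v in p1.items()} == {k: v.counts for k, v in p2.items()}
    # mismatch bookkeeping survives the round trip
    by_id = {a.read_id: a for a in back}
    for a in alns:
        b = by_id[a.read_id]
        assert (b.n_mismatches, b.mismatch_positions, b.target_start, b.strand) == (
            a.n_mismatches, a.mismatch_positions, a.target_start, a.strand)


def test_sam_skips_unmapped_records(tmp_path):
    sam = tmp_path / "u.sam"
    sam.write_text("@HD\tVN:1.6\n@SQ\tSN:s1\tLN:50\nr1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")
    assert read_external_alignments(sam) == []


def test_sam_without_nm_skipped(tmp_path, caplog):
    sam = tmp_path / "x.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:s1\tLN:50\n"
        "r1\t0\ts1\t1\t255\t4M\t*\t0\t0\tACGT\tIIII\n"
    )
    with caplog.at_level("WARNING"):
        assert read_external_alignments(sam) == []
    assert "skipped 1" in caplog.text


def test_pileup_tsv_roundtrip(tmp_path):
    p = SitePileup("s1", "i1", "DNA", {"A": 5, "G": 2})
    path = tmp_path / "p.tsv"
    align.write_pileup_tsv({("s1", "i1"): p}, path)
    back = align.read_pileup_tsv(path)
    assert back[("s1", "i1")].counts == {"A": 5, "G": 2}
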