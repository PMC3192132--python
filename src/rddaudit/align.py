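"""Ungapped read mapping against flank or transcript databases, and pileups.

`map_reads` is a desk-scale stand-in for a short-read mapper: it performs an
exact minimum-Hamming-distance search of each read and its reverse complement
over every ungapped placement on every target.  Exactness at a mismatch bound
m is guaranteed by pigeonhole seeding: a read of length L is split into m+1
disjoint chunks of length L // (m+1); any placement with <= m mismatches
matches at least one chunk exactly, so an index of target k-mers finds every
qualifying placement.

Tie policy (documented divergence knob): a read whose best distance is reached
on two distinct targets is discarded as ambiguous; ties within one target are
broken leftmost, forward strand before reverse.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from . import _seq
from .io import RddSite
from .simulate import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 49


class CoordinateError(ValueError):
    """A site position lies outside its reference sequence."""


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True, slots=True)
class FlankEntry:
    site_id: str
    seq: str           # transcript-strand flank sequence; site nucleotide A at rdd_offset
    rdd_offset: int
    strand: str
    chrom: str
    start: int         # 0-based start of the extracted window on the forward genome


@dataclasses.dataclass
class FlankDatabase:
    entries: list[FlankEntry]
    flank: int = DEFAULT_FLANK

    def __len__(self) -> int:
        return len(self.entries)

    def as_dict(self) -> dict[str, str]:
        return {e.site_id: e.seq for e in self.entries}

    def rdd_offsets(self) -> dict[str, int]:
        return {e.site_id: e.rdd_offset for e in self.entries}


@dataclasses.dataclass
class FlankBuildResult:
    database: FlankDatabase
    reference_mismatch: list[str]  # site_ids where the reference shows nucleotide B
    inconsistent: list[str]        # reference shows neither A nor B; excluded


@dataclasses.dataclass(slots=True)
class ReadAlignment:
    read_id: str
    target: str
    target_start: int
    strand: str
    n_mismatches: int
    mismatch_positions: tuple[int, ...]  # target coordinates
    aligned_seq: str                     # read presented on the target strand
    covers_rdd: bool = False
    base_at_rdd: str | None = None
    individual: str | None = None


@dataclasses.dataclass(slots=True)
class SitePileup:
    site_id: str
    individual: str
    source: str  # "RNA" | "DNA"
    counts: dict[str, int] = dataclasses.field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def n_of(self, nt: str) -> int:
        return self.counts.get(nt, 0)

    def abo(self, a_nt: str, b_nt: str) -> tuple[int, int, int]:
        """(n_A, n_B, n_other) for the site's genomic and RDD nucleotides."""
        n_a = self.n_of(a_nt)
        n_b = self.n_of(b_nt)
        return n_a, n_b, self.total - n_a - n_b

    def add(self, nt: str, n: int = 1) -> None:
        self.counts[nt] = self.counts.get(nt, 0) + n


def build_flank_db(
    sites: Sequence[RddSite],
    reference: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> FlankBuildResult:
    """Extract per-site flank windows from the reference.

    Sites whose reference base equals the RDD nucleotide B are diverted to the
    reference-mismatch list; sites whose reference base is neither A nor B are
    excluded as inconsistent.  Minus-strand entries are reverse-complemented so
    A and B are on the transcript strand.  Windows near sequence ends are
    truncated rather than excluded.
    """
    entries: list[FlankEntry] = []
    ref_mismatch: list[str] = []
    inconsistent: list[str] = []
    for site in sites:
        if site.chrom not in reference:
            raise CoordinateError(f"site {site.site_id}: unknown sequence {site.chrom!r}")
        chrom_seq = reference[site.chrom]
        pos0 = site.pos - 1
        if not 0 <= pos0 < len(chrom_seq):
            raise CoordinateError(
                f"site {site.site_id}: position {site.pos} outside {site.chrom} "
                f"(length {len(chrom_seq)})"
            )
        start = max(0, pos0 - flank)
        end = min(len(chrom_seq), pos0 + flank + 1)
        window = chrom_seq[start:end]
        offset = pos0 - start
        if site.strand == "-":
            window = _seq.revcomp(window)
            offset = len(window) - 1 - offset
        ref_base = window[offset]
        if ref_base == site.rdd_nt:
            ref_mismatch.append(site.site_id)
        elif ref_base == site.ref_nt:
            entries.append(FlankEntry(site.site_id, window, offset, site.strand, site.chrom, start))
        else:
            inconsistent.append(site.site_id)
            logger.warning(
                "site %s: reference shows %s, neither A=%s nor B=%s; excluded",
                site.site_id, ref_base, site.ref_nt, site.rdd_nt,
            )
    return FlankBuildResult(FlankDatabase(entries, flank), ref_mismatch, inconsistent)


# --------------------------------------------------------------------------
# mapping
# --------------------------------------------------------------------------

def _normalise_targets(targets) -> tuple[list[str], list[np.ndarray], dict[str, tuple[int, str]]]:
    """Returns (ids, code arrays, rdd info {target: (offset, a_nt)})."""
    rdd_info: dict[str, tuple[int, str]] = {}
    if isinstance(targets, FlankDatabase):
        ids = [e.site_id for e in targets.entries]
        codes = [_seq.encode(e.seq) for e in targets.entries]
        rdd_info = {e.site_id: (e.rdd_offset, e.seq[e.rdd_offset]) for e in targets.entries}
    elif isinstance(targets, Mapping):
        ids = list(targets)
        codes = [_seq.encode(targets[t]) for t in ids]
    else:
        raise TypeError(f"unsupported target collection: {type(targets)!r}")
    if not ids:
        raise ConfigurationError("empty target database")
    return ids, codes, rdd_info


def _reads_matrix(reads) -> tuple[list[str], np.ndarray]:
    if isinstance(reads, ReadSet):
        return list(reads.ids), reads.codes
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rid, seq in reads:
        ids.append(rid)
        rows.append(_seq.encode(seq))
    if not rows:
        return ids, np.empty((0, 0), dtype=np.uint8)
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ConfigurationError("mixed read lengths in one batch; map per length group")
    return ids, np.vstack(rows)


def _candidate_hits(
    chunk_keys: np.ndarray, chunk_valid: np.ndarray, chunk_off: int,
    sorted_keys: np.ndarray, key_tidx: np.ndarray, key_pos: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand index matches of one read-chunk column into candidate diagonals."""
    lo = np.searchsorted(sorted_keys, chunk_keys, side="left")
    hi = np.searchsorted(sorted_keys, chunk_keys, side="right")
    counts = np.where(chunk_valid, hi - lo, 0)
    total = int(counts.sum())
    if total == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, e
    read_i = np.repeat(np.arange(len(chunk_keys)), counts)
    # ragged ranges lo[i] .. lo[i]+counts[i]
    base = np.repeat(lo, counts)
    csum = np.concatenate(([0], np.cumsum(counts)))
    within = np.arange(total) - np.repeat(csum[:-1], counts)
    flat = base + within
    return read_i, key_tidx[flat], key_pos[flat] - chunk_off


def map_reads(
    reads,
    targets,
    max_mismatches: int,
    individual: str | None = None,
) -> list[ReadAlignment]:
    """Best ungapped placement of each read (and its reverse complement).

    Returns one alignment per unambiguously placed read with Hamming distance
    <= ``max_mismatches``.  See module docstring for the tie policy.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    tids, tcodes, rdd_info = _normalise_targets(targets)
    read_ids, R = _reads_matrix(reads)
    if R.shape[0] == 0:
        return []
    L = R.shape[1]
    tlens = np.array([len(c) for c in tcodes])
    max_tlen = int(tlens.max())
    T = np.full((len(tcodes), max_tlen), 6, dtype=np.uint8)
    for i, c in enumerate(tcodes):
        T[i, : len(c)] = c

    k = L // (max_mismatches + 1)
    k = min(k, 24)  # keep base-4 keys inside int64
    if k < 4:
        ri, st, ti, start, mism = _scan_all_placements(R, T, tlens, max_mismatches)
    else:
        ri, st, ti, start, mism = _seeded_placements(R, T, tlens, k, max_mismatches)

    return _emit_alignments(
        read_ids, R, T, tids, tlens, rdd_info, ri, st, ti, start, mism, individual
    )


def _seeded_placements(R, T, tlens, k, max_mismatches):
    n_targets, max_tlen = T.shape
    L = R.shape[1]
    # index all forward target k-mers
    keys_parts, tidx_parts, pos_parts = [], [], []
    for i in range(n_targets):
        keys, valid = _seq.kmer_keys(T[i, : tlens[i]], k)
        idx = np.flatnonzero(valid)
        keys_parts.append(keys[idx])
        tidx_parts.append(np.full(len(idx), i, dtype=np.int64))
        pos_parts.append(idx.astype(np.int64))
    all_keys = np.concatenate(keys_parts)
    all_tidx = np.concatenate(tidx_parts)
    all_pos = np.concatenate(pos_parts)
    order = np.argsort(all_keys, kind="stable")
    sorted_keys, key_tidx, key_pos = all_keys[order], all_tidx[order], all_pos[order]

    pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    RC = _seq.comp_codes(R)[:, ::-1]
    cand: list[tuple[np.ndarray, np.ndarray, np.ndarray, int]] = []
    n_chunks = min(max_mismatches + 1, L // k)
    for strand, M in ((0, R), (1, RC)):
        for c in range(n_chunks):
            off = c * k
            chunk = M[:, off : off + k]
            valid = ~np.any(chunk >= 4, axis=1)
            keys = chunk.astype(np.int64) @ pows
            ri, ti, start = _candidate_hits(keys, valid, off, sorted_keys, key_tidx, key_pos)
            ok = (start >= 0) & (start <= tlens[ti] - L)
            cand.append((ri[ok], ti[ok], start[ok], strand))

    if not any(len(c[0]) for c in cand):
        e = np.empty(0, dtype=np.int64)
        return e, e, e, e, e
    ri = np.concatenate([c[0] for c in cand])
    ti = np.concatenate([c[1] for c in cand])
    start = np.concatenate([c[2] for c in cand])
    st = np.concatenate([np.full(len(c[0]), c[3], dtype=np.int64) for c in cand])

    packed = ((ri * 2 + st) * len(tlens) + ti) * (T.shape[1] + 1) + start
    _, uniq = np.unique(packed, return_index=True)
    ri, st, ti, start = ri[uniq], st[uniq], ti[uniq], start[uniq]

    # verify candidates in batches to bound memory
    mism = np.empty(len(ri), dtype=np.int64)
    span = np.arange(L)
    batch = max(2_000_000 // max(L, 1), 1)
    for lo in range(0, len(ri), batch):
        sl = slice(lo, min(lo + batch, len(ri)))
        win = T[ti[sl, None], start[sl, None] + span]
        rd = np.where(st[sl, None] == 0, R[ri[sl]], RC[ri[sl]])
        mism[sl] = np.count_nonzero((win != rd) | (win >= 4) | (rd >= 4), axis=1)
    keep = mism <= max_mismatches
    return ri[keep], st[keep], ti[keep], start[keep], mism[keep]


def _scan_all_placements(R, T, tlens, max_mismatches):
    """Exhaustive placement enumeration (fallback for very short reads)."""
    L = R.shape[1]
    RC = _seq.comp_codes(R)[:, ::-1]
    ris, sts, tis, starts, misms = [], [], [], [], []
    for i in range(T.shape[0]):
        n_off = tlens[i] - L + 1
        if n_off <= 0:
            continue
        win = np.lib.stride_tricks.sliding_window_view(T[i, : tlens[i]], L)
        for strand, M in ((0, R), (1, RC)):
            # (n_reads, n_off) mismatch counts
            d = np.count_nonzero(
                (M[:, None, :] != win[None, :, :]) | (M[:, None, :] >= 4) | (win[None, :, :] >= 4),
                axis=2,
            )
            r, o = np.nonzero(d <= max_mismatches)
            ris.append(r)
            sts.append(np.full(len(r), strand, dtype=np.int64))
            tis.append(np.full(len(r), i, dtype=np.int64))
            starts.append(o)
            misms.append(d[r, o])
    if not ris:
        e = np.empty(0, dtype=np.int64)
        return e, e, e, e, e
    return (
        np.concatenate(ris), np.concatenate(sts), np.concatenate(tis),
        np.concatenate(starts), np.concatenate(misms),
    )


def _emit_alignments(
    read_ids, R, T, tids, tlens, rdd_info, ri, st, ti, start, mism, individual
) -> list[ReadAlignment]:
    if len(ri) == 0:
        return []
    L = R.shape[1]
    # best placement per read: order by (read, mismatches, start, strand)
    order = np.lexsort((st, start, mism, ri))
    ri, st, ti, start, mism = ri[order], st[order], ti[order], start[order], mism[order]
    first = np.concatenate(([True], ri[1:] != ri[:-1]))
    group = np.cumsum(first) - 1
    best_mism = mism[np.flatnonzero(first)][group]
    best_tidx = ti[np.flatnonzero(first)][group]
    # ambiguous: any minimum-distance placement on a different target
    is_min = mism == best_mism
    ambiguous_rows = is_min & (ti != best_tidx)
    ambiguous_reads = np.zeros(R.shape[0], dtype=bool)
    ambiguous_reads[ri[ambiguous_rows]] = True

    winners = np.flatnonzero(first)
    winners = winners[~ambiguous_reads[ri[winners]]]
    if len(winners) == 0:
        return []
    w_ri, w_st, w_ti, w_start, w_mism = (
        ri[winners], st[winners], ti[winners], start[winners], mism[winners],
    )

    RC = _seq.comp_codes(R)[:, ::-1]
    span = np.arange(L)
    win = T[w_ti[:, None], w_start[:, None] + span]
    rd = np.where(w_st[:, None] == 0, R[w_ri], RC[w_ri])
    mask = (win != rd) | (win >= 4) | (rd >= 4)
    rows, cols = np.nonzero(mask)
    split = np.searchsorted(rows, np.arange(len(winners) + 1))

    out: list[ReadAlignment] = []
    for j in range(len(winners)):
        tname = tids[w_ti[j]]
        tstart = int(w_start[j])
        positions = tuple(int(c) + tstart for c in cols[split[j] : split[j + 1]])
        aligned = _seq.decode(rd[j])
        aln = ReadAlignment(
            read_id=read_ids[w_ri[j]],
            target=tname,
            target_start=tstart,
            strand="+-"[int(w_st[j])],
            n_mismatches=int(w_mism[j]),
            mismatch_positions=positions,
            aligned_seq=aligned,
            individual=individual,
        )
        if tname in rdd_info:
            off, _a = rdd_info[tname]
            if tstart <= off < tstart + L:
                aln.covers_rdd = True
                aln.base_at_rdd = aligned[off - tstart]
        out.append(aln)
    return out


def filter_genomic_alignments(
    alignments: Iterable[ReadAlignment],
    database: FlankDatabase,
) -> list[ReadAlignment]:
    """Keep alignments with at most one mismatch besides one at the RDD column."""
    offsets = database.rdd_offsets()
    kept = []
    for aln in alignments:
        rdd_off = offsets.get(aln.target)
        discount = 1 if (rdd_off is not None and rdd_off in aln.mismatch_positions) else 0
        if aln.n_mismatches - discount <= 1:
            kept.append(aln)
    return kept


def pileup(
    alignments: Iterable[ReadAlignment],
    sites_by_target: Mapping[str, Sequence[tuple[str, int]]],
    source: str,
    max_mismatches: int | None = None,
    individual: str | None = None,
) -> dict[tuple[str, str], SitePileup]:
    """Per-(site, individual) nucleotide counts at each site column.

    ``sites_by_target`` maps a target id to [(site_id, 0-based offset)] pairs;
    a flank database contributes one pair per entry, a transcript database can
    carry several sites per transcript.  ``max_mismatches`` drops noisier
    alignments first (the RNA side uses 2).
    """
    out: dict[tuple[str, str], SitePileup] = {}
    for aln in alignments:
        if max_mismatches is not None and aln.n_mismatches > max_mismatches:
            continue
        ind = aln.individual or individual or "unknown"
        for site_id, off in sites_by_target.get(aln.target, ()):
            if aln.target_start <= off < aln.target_start + len(aln.aligned_seq):
                key = (site_id, ind)
                pile = out.get(key)
                if pile is None:
                    pile = out[key] = SitePileup(site_id, ind, source)
                pile.add(aln.aligned_seq[off - aln.target_start])
    return out


def flank_site_map(database: FlankDatabase) -> dict[str, list[tuple[str, int]]]:
    return {e.site_id: [(e.site_id, e.rdd_offset)] for e in database.entries}


# --------------------------------------------------------------------------
# SAM interchange
# --------------------------------------------------------------------------

def write_sam(
    alignments: Iterable[ReadAlignment],
    targets,
    path: str | Path,
) -> None:
    """Minimal SAM dialect: @SQ per target, ungapped CIGAR, NM tag."""
    tids, tcodes, _ = _normalise_targets(targets)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t, "LN": len(c)} for t, c in zip(tids, tcodes)],
    }
    index = {t: i for i, t in enumerate(tids)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = aln.read_id
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = index[aln.target]
            rec.reference_start = aln.target_start
            rec.mapping_quality = 255
            rec.cigarstring = f"{len(aln.aligned_seq)}M"
            rec.query_sequence = aln.aligned_seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(aln.aligned_seq))
            tags = [("NM", aln.n_mismatches)]
            if aln.individual:
                tags.append(("RG", aln.individual))
            rec.set_tags(tags)
            fh.write(rec)


def read_external_alignments(
    path: str | Path,
    targets=None,
    individual: str | None = None,
) -> list[ReadAlignment]:
    """Read SAM records back into alignments.

    When target sequences are supplied, mismatch positions and counts are
    recomputed from SEQ against the target; otherwise the NM tag supplies the
    count (records without NM are skipped and counted in the log).
    """
    tseqs: dict[str, str] = {}
    rdd_info: dict[str, tuple[int, str]] = {}
    if targets is not None:
        tids, tcodes, rdd_info = _normalise_targets(targets)
        tseqs = {t: _seq.decode(c) for t, c in zip(tids, tcodes)}
    out: list[ReadAlignment] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            tname = rec.reference_name
            seq = rec.query_sequence.upper()
            start = rec.reference_start
            if tname in tseqs:
                tslice = tseqs[tname][start : start + len(seq)]
                mask = _seq.mismatch_mask(_seq.encode(seq), _seq.encode(tslice))
                positions = tuple(int(i) + start for i in np.flatnonzero(mask))
                nm = len(positions)
            elif rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
                positions = ()
            else:
                skipped += 1
                continue
            ind = individual
            if rec.has_tag("RG"):
                ind = str(rec.get_tag("RG"))
            aln = ReadAlignment(
                read_id=rec.query_name,
                target=tname,
                target_start=start,
                strand="-" if rec.is_reverse else "+",
                n_mismatches=nm,
                mismatch_positions=positions,
                aligned_seq=seq,
                individual=ind,
            )
            if tname in rdd_info:
                off, _a = rdd_info[tname]
                if start <= off < start + len(seq):
                    aln.covers_rdd = True
                    aln.base_at_rdd = seq[off - start]
            out.append(aln)
    if skipped:
        logger.warning("skipped %d SAM records lacking mismatch information", skipped)
    return out


def write_pileup_tsv(pileups: Mapping[tuple[str, str], SitePileup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tindividual\tsource\tcount_A\tcount_C\tcount_G\tcount_T\tcount_N\n")
        for (_sid, _ind), p in sorted(pileups.items()):
            counts = "\t".join(str(p.n_of(nt)) for nt in "ACGTN")
            fh.write(f"{p.site_id}\t{p.individual}\t{p.source}\t{counts}\n")


def read_pileup_tsv(path: str | Path) -> dict[tuple[str, str], SitePileup]:
    out: dict[tuple[str, str], SitePileup] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            p = SitePileup(row["site_id"], row["individual"], row["source"])
            for nt in "ACGTN":
                n = int(row[f"count_{nt}"])
                if n:
                    p.add(nt, n)
            out[(p.site_id, p.individual)] = p
    return out
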