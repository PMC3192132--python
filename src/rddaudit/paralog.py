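"""Search site flank queries against the reference genome and classify hits.

The stand-in search is ungapped: a hit is a full-length placement of the
99-bp flank query on either genome strand with identity strictly greater
than ``min_identity`` and aligned length at least ``min_length``.  Seeding
uses disjoint query chunks sized so that any placement within the allowed
mismatch budget is guaranteed to share one exact chunk with the genome
(pigeonhole), making the search equivalent to an exhaustive windowed
Hamming scan.  Readers for PSL and BLAST tabular output allow substituting
a real aligner at the hit level.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _seq
from .align import FlankDatabase, FlankEntry
from .io import Interval

MATCHING_B = "matching_B"
NON_MATCHING = "non_matching"

STATUS_REF_MISMATCH = "reference_mismatch"
STATUS_MATCHING = "has_matching_paralog"
STATUS_NON_MATCHING_ONLY = "has_nonmatching_paralog_only"
STATUS_NONE = "no_paralog"


@dataclasses.dataclass(slots=True)
class ParalogHit:
    site_id: str
    chrom: str
    start: int            # 0-based, forward genome coordinates
    end: int              # half-open
    strand: str
    aligned_length: int
    identity: float
    covers_rdd_column: bool
    base_at_rdd_column: str | None  # in the query (transcript-strand) frame
    classification: str
    rdd_column_pos: int | None = None  # 0-based genomic position aligned to the RDD column
    in_gene: bool = False
    in_transcribed: bool = False


def _classify(base: str | None, rdd_nt: str, covers: bool) -> str:
    return MATCHING_B if covers and base == rdd_nt else NON_MATCHING


def search_flanks(
    database: FlankDatabase,
    reference: Mapping[str, str],
    rdd_nts: Mapping[str, str],
    min_identity: float = 0.9,
    min_length: int = 50,
    seed_k: int | None = None,
) -> list[ParalogHit]:
    """All qualifying genome placements of every flank query.

    ``rdd_nts`` maps site_id to the RDD nucleotide B (transcript strand) so
    hits can be classified.  The query's own locus is never reported.
    """
    chrom_codes = {c: _seq.encode(s) for c, s in reference.items()}
    # per-(chrom, k) sorted k-mer index, built lazily
    indexes: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    def chrom_index(chrom: str, k: int) -> tuple[np.ndarray, np.ndarray]:
        key = (chrom, k)
        if key not in indexes:
            keys, valid = _seq.kmer_keys(chrom_codes[chrom], k)
            idx = np.flatnonzero(valid)
            order = np.argsort(keys[idx], kind="stable")
            indexes[key] = (keys[idx][order], idx[order].astype(np.int64))
        return indexes[key]

    hits: list[ParalogHit] = []
    for entry in database.entries:
        L = len(entry.seq)
        if L < min_length:
            continue
        # identity > min_identity (strict)  <=>  mismatches < L * (1 - min_identity)
        budget = L * (1.0 - min_identity)
        max_mm = int(np.ceil(budget)) - 1 if float(budget).is_integer() else int(np.floor(budget))
        if max_mm < 0:
            continue
        k = max(4, min(L // (max_mm + 1), 24))
        q_fwd = _seq.encode(entry.seq)
        q_rev = _seq.revcomp_codes(q_fwd)
        n_chunks = min(max_mm + 1, L // k)
        for chrom, codes in chrom_codes.items():
            if len(codes) < L:
                continue
            sorted_keys, sorted_pos = chrom_index(chrom, k)
            pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
            for strand, q in (("+", q_fwd), ("-", q_rev)):
                cand: set[int] = set()
                for c in range(n_chunks):
                    off = c * k
                    chunk = q[off : off + k]
                    if np.any(chunk >= 4):
                        continue
                    ckey = int(chunk.astype(np.int64) @ pows)
                    lo = int(np.searchsorted(sorted_keys, ckey, side="left"))
                    hi = int(np.searchsorted(sorted_keys, ckey, side="right"))
                    for p in sorted_pos[lo:hi]:
                        g = int(p) - off
                        if 0 <= g <= len(codes) - L:
                            cand.add(g)
                for g in sorted(cand):
                    win = codes[g : g + L]
                    mm = _seq.hamming(q, win)
                    if mm > max_mm:
                        continue
                    if chrom == entry.chrom and g == entry.start:
                        continue  # self locus
                    identity = (L - mm) / L
                    off_in_q = entry.rdd_offset
                    if strand == "+":
                        col_pos = g + off_in_q
                        base = _seq.BASES[win[off_in_q]] if win[off_in_q] < 4 else "N"
                    else:
                        col_pos = g + (L - 1 - off_in_q)
                        code = win[L - 1 - off_in_q]
                        base = _seq.revcomp(_seq.BASES[code]) if code < 4 else "N"
                    b_nt = rdd_nts.get(entry.site_id, "")
                    hits.append(
                        ParalogHit(
                            site_id=entry.site_id,
                            chrom=chrom,
                            start=g,
                            end=g + L,
                            strand=strand,
                            aligned_length=L,
                            identity=identity,
                            covers_rdd_column=True,
                            base_at_rdd_column=base,
                            classification=_classify(base, b_nt, True),
                            rdd_column_pos=col_pos,
                        )
                    )
    return hits


def classify_site(
    site_id: str,
    hits: Iterable[ParalogHit],
    reference_mismatch: Iterable[str],
) -> str:
    """Site-level paralog status with fixed precedence.

    reference_mismatch > has_matching_paralog > has_nonmatching_paralog_only >
    no_paralog.  Hits not spanning the RDD column contribute to no category.
    """
    if site_id in set(reference_mismatch):
        return STATUS_REF_MISMATCH
    spanning = [h for h in hits if h.site_id == site_id and h.covers_rdd_column]
    if any(h.classification == MATCHING_B for h in spanning):
        return STATUS_MATCHING
    if spanning:
        return STATUS_NON_MATCHING_ONLY
    return STATUS_NONE


def interval_lookup(intervals: Sequence[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        # merge so a simple searchsorted answers membership
        merged: list[list[int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        out[chrom] = (starts, ends)
    return out


def point_in_intervals(
    lookup: Mapping[str, tuple[np.ndarray, np.ndarray]], chrom: str, pos0: int
) -> bool:
    if chrom not in lookup:
        return False
    starts, ends = lookup[chrom]
    i = int(np.searchsorted(starts, pos0, side="right")) - 1
    return bool(i >= 0 and pos0 < ends[i])


def annotate_hits(
    hits: Sequence[ParalogHit],
    gene_intervals: Sequence[Interval],
    transcribed_intervals: Sequence[Interval],
) -> dict[str, dict[str, float | int]]:
    """Flag each hit's RDD-column position against the interval sets and return
    per-classification counts and fractions."""
    genes = interval_lookup(gene_intervals)
    transcribed = interval_lookup(transcribed_intervals)
    for h in hits:
        if h.rdd_column_pos is None:
            continue
        h.in_gene = point_in_intervals(genes, h.chrom, h.rdd_column_pos)
        h.in_transcribed = point_in_intervals(transcribed, h.chrom, h.rdd_column_pos)
    summary: dict[str, dict[str, float | int]] = {}
    for group in (MATCHING_B, NON_MATCHING):
        sub = [h for h in hits if h.classification == group]
        n = len(sub)
        n_gene = int(sum(bool(h.in_gene) for h in sub))
        n_tx = int(sum(bool(h.in_transcribed) for h in sub))
        summary[group] = {
            "n_hits": n,
            "n_in_gene": n_gene,
            "n_in_transcribed": n_tx,
            "frac_in_gene": n_gene / n if n else 0.0,
            "frac_in_transcribed": n_tx / n if n else 0.0,
        }
    return summary


# --------------------------------------------------------------------------
# readers for external search tools
# --------------------------------------------------------------------------

def _hit_from_coords(
    entry: FlankEntry,
    reference: Mapping[str, str],
    rdd_nt: str,
    chrom: str,
    qstart0: int,
    sstart0: int,
    length: int,
    strand: str,
    identity: float,
) -> ParalogHit:
    """Build a hit from an ungapped block in query/subject coordinates."""
    off = entry.rdd_offset
    covers = qstart0 <= off < qstart0 + length
    base = None
    col_pos = None
    if covers:
        if strand == "+":
            col_pos = sstart0 + (off - qstart0)
            base = reference[chrom][col_pos]
        else:
            col_pos = sstart0 + length - 1 - (off - qstart0)
            base = _seq.revcomp(reference[chrom][col_pos])
    return ParalogHit(
        site_id=entry.site_id,
        chrom=chrom,
        start=sstart0,
        end=sstart0 + length,
        strand=strand,
        aligned_length=length,
        identity=identity,
        covers_rdd_column=covers,
        base_at_rdd_column=base,
        classification=_classify(base, rdd_nt, covers),
        rdd_column_pos=col_pos,
    )


def read_blast_tab(
    path: str | Path,
    database: FlankDatabase,
    reference: Mapping[str, str],
    rdd_nts: Mapping[str, str],
    min_identity: float = 0.9,
    min_length: int = 50,
) -> list[ParalogHit]:
    """BLAST ``-outfmt 6`` rows as hits; gapped rows are skipped."""
    entries = {e.site_id: e for e in database.entries}
    hits: list[ParalogHit] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            qid, sid = f[0], f[1]
            pident, length = float(f[2]) / 100.0, int(f[3])
            gapopen = int(f[5])
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            if qid not in entries or gapopen > 0 or (qend - qstart) != abs(send - sstart):
                continue
            if length < min_length or pident <= min_identity:
                continue
            entry = entries[qid]
            if sstart <= send:
                hits.append(_hit_from_coords(entry, reference, rdd_nts.get(qid, ""),
                                             sid, qstart - 1, sstart - 1, length, "+", pident))
            else:
                hits.append(_hit_from_coords(entry, reference, rdd_nts.get(qid, ""),
                                             sid, qstart - 1, send - 1, length, "-", pident))
    return [h for h in hits if not (h.chrom == entries[h.site_id].chrom and h.start == entries[h.site_id].start)]


def read_psl(
    path: str | Path,
    database: FlankDatabase,
    reference: Mapping[str, str],
    rdd_nts: Mapping[str, str],
    min_identity: float = 0.9,
    min_length: int = 50,
) -> list[ParalogHit]:
    """Single-block PSL rows as hits (multi-block/gapped rows are skipped)."""
    entries = {e.site_id: e for e in database.entries}
    hits: list[ParalogHit] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 21 or not f[0].isdigit():
                continue  # header lines
            matches, mismatches = int(f[0]), int(f[1])
            strand, qid, sid = f[8], f[9], f[13]
            block_count = int(f[17])
            if qid not in entries or block_count != 1:
                continue
            length = matches + mismatches
            if length < min_length:
                continue
            identity = matches / length if length else 0.0
            if identity <= min_identity:
                continue
            qstart0 = int(f[19].rstrip(",").split(",")[0])
            tstart0 = int(f[20].rstrip(",").split(",")[0])
            entry = entries[qid]
            if strand == "+":
                hits.append(_hit_from_coords(entry, reference, rdd_nts.get(qid, ""),
                                             sid, qstart0, tstart0, length, "+", identity))
            else:
                # PSL block qStarts for '-' are in reverse-complemented query coords
                q0 = len(entry.seq) - (qstart0 + length)
                hits.append(_hit_from_coords(entry, reference, rdd_nts.get(qid, ""),
                                             sid, q0, tstart0, length, "-", identity))
    return [h for h in hits if not (h.chrom == entries[h.site_id].chrom and h.start == entries[h.site_id].start)]


def write_hits_tsv(hits: Iterable[ParalogHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "site_id\tchrom\tstart\tend\tstrand\taligned_length\tidentity\t"
            "covers_rdd_column\tbase_at_rdd_column\tclassification\t"
            "rdd_column_pos\tin_gene\tin_transcribed\n"
        )
        for h in hits:
            fh.write(
                f"{h.site_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.aligned_length}\t{h.identity:.6f}\t{int(h.covers_rdd_column)}\t"
                f"{h.base_at_rdd_column or '.'}\t{h.classification}\t"
                f"{'.' if h.rdd_column_pos is None else h.rdd_column_pos}\t"
                f"{int(h.in_gene)}\t{int(h.in_transcribed)}\n"
            )
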