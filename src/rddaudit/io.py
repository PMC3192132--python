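"""Plain-text format I/O: FASTA, FASTQ, BED intervals, and the site/truth TSVs.

Coordinate conventions: BED is 0-based half-open; site tables are 1-based
inclusive with an explicit strand column. Everything internal is 0-based.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

SITE_COLUMNS = ["site_id", "chrom", "pos", "strand", "ref_nt", "rdd_nt"]
TRUTH_COLUMNS = ["site_id", "cause", "donor_locus", "carriers"]


@dataclasses.dataclass(frozen=True, slots=True)
class RddSite:
    """One candidate RNA-DNA difference site.

    ``pos`` is 1-based on ``chrom``; ``ref_nt`` (A) and ``rdd_nt`` (B) are given
    on the transcript strand indicated by ``strand``.
    """

    site_id: str
    chrom: str
    pos: int
    strand: str
    ref_nt: str
    rdd_nt: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for site {self.site_id}")
        if self.ref_nt == self.rdd_nt:
            raise ValueError(f"site {self.site_id}: ref and RDD nucleotide identical")

    @property
    def substitution(self) -> str:
        return f"{self.ref_nt}>{self.rdd_nt}"


@dataclasses.dataclass(frozen=True, slots=True)
class Interval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    name: str = "."


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs; qualities are ignored downstream."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_bed(path: str | Path) -> list[Interval]:
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: bad interval [{start},{end})")
            name = fields[3] if len(fields) > 3 else "."
            intervals.append(Interval(fields[0], start, end, name))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_site_table(path: str | Path) -> list[RddSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "site_id": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns: {sorted(missing)}")
    return [
        RddSite(r.site_id, r.chrom, int(r.pos), r.strand, r.ref_nt, r.rdd_nt)
        for r in df.itertuples()
    ]


def write_site_table(sites: Iterable[RddSite], path: str | Path) -> None:
    rows = [dataclasses.astuple(s) for s in sites]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)
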