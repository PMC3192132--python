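"""Synthetic cohorts with known ground truth.

A cohort is one reference chromosome carrying annotated genes, a set of
diploid individuals, and planted candidate RDD sites of four causes:

* ``ref_paralog``       — an unannotated but transcribed reference paralog of a
                          gene differs from it at one trap position, showing the
                          RDD nucleotide.
* ``polymorphic_paralog`` — the reference paralog matches the gene at the trap,
                          but some individuals carry a SNP in the paralog that
                          creates the RDD nucleotide.
* ``cnv_paralog``       — a segregating duplication of the gene, absent from
                          the reference, carries the RDD nucleotide.
* ``true_edit``         — a genuine editing event applied to a fraction of
                          transcripts; no genomic source exists.

Each planted confounder differs from its parent gene at exactly one designated
trap position (plus background divergence elsewhere), so the truth table is
unambiguous.  Reads carry their provenance in the read name
(``<source>:<start0>:<serial>``) for oracle tests.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np

from . import _seq
from .io import Interval, RddSite

CAUSES = ("true_edit", "ref_paralog", "polymorphic_paralog", "cnv_paralog")

CHROM = "chr1"


class CohortSizingError(ValueError):
    """Genome too small to place the requested genes and paralog copies."""


@dataclasses.dataclass(frozen=True)
class SimConfig:
    genome_length: int = 200_000
    n_genes: int = 40
    transcript_length: int = 1000
    paralog_fraction: float = 0.25
    paralog_divergence: float = 0.01
    polymorphic_paralog_fraction: float = 0.5
    paralog_snp_freq: float = 0.5
    paralogs_transcribed: bool = True
    n_individuals: int = 5
    cnv_fraction: float = 0.1
    cnv_allele_freq: float = 0.3
    snp_rate: float = 0.0005
    n_true_edits: int = 5
    edit_fraction: float = 0.5
    # force every true edit to one substitution type, e.g. "A>G" (transcript
    # strand); None keeps types random
    edit_substitution: str | None = None
    rna_read_length: int = 50
    rna_depth: float = 30.0
    dna_depth: float = 20.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "paralog_fraction",
            "paralog_divergence",
            "polymorphic_paralog_fraction",
            "paralog_snp_freq",
            "cnv_fraction",
            "cnv_allele_freq",
            "snp_rate",
            "edit_fraction",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("genome_length", "n_genes", "transcript_length", "n_individuals", "rna_read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_edits < 0:
            raise ValueError("n_true_edits must be >= 0")
        if self.rna_depth <= 0 or self.dna_depth <= 0:
            raise ValueError("depths must be positive")
        if self.rna_read_length > self.transcript_length:
            raise ValueError("rna_read_length exceeds transcript length")


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    site_id: str
    cause: str
    donor_locus: str | None  # "chrom:pos1" of the explaining sequence; None for true_edit
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.cause not in CAUSES:
            raise ValueError(f"unknown cause {self.cause!r}")
        if (self.cause == "true_edit") != (self.donor_locus is None):
            raise ValueError("donor_locus must be absent iff cause is true_edit")
        if not self.carriers:
            raise ValueError("carriers must be non-empty")


@dataclasses.dataclass(frozen=True)
class _Gene:
    gene_id: str
    start: int          # 0-based on reference
    strand: str


@dataclasses.dataclass(frozen=True)
class _ParalogCopy:
    gene_id: str
    start: int          # 0-based on reference; -1 for CNV copies (absent from reference)
    forward: bool       # inserted in the gene's genomic frame (True) or reverse-complemented
    codes: np.ndarray   # copy sequence in its inserted frame (CNV: gene genomic frame)
    trap_offset: int    # offset of the trap within `codes`


@dataclasses.dataclass
class Cohort:
    """Everything `simulate_cohort` plants, in memory."""

    config: SimConfig
    reference: dict[str, str]
    sites: list[RddSite]
    truth: list[TruthRecord]
    individuals: list[str]
    genes: list[_Gene]
    gene_intervals: list[Interval]
    transcribed_intervals: list[Interval]
    dup_intervals: list[Interval]
    # per individual, per haplotype (0/1): {pos0: alt_code} on the reference chromosome
    snps: dict[str, tuple[dict[int, int], dict[int, int]]]
    # gene_id -> number of extra duplication alleles (0..2) per individual
    cnv_alleles: dict[str, dict[str, int]]
    ref_paralogs: dict[str, _ParalogCopy]   # gene_id -> reference copy
    cnv_copies: dict[str, _ParalogCopy]     # gene_id -> segregating copy
    edit_sites: dict[str, list[tuple[str, int, int]]]  # gene_id -> [(site_id, tx_offset, b_code)]

    def transcript_db(self) -> dict[str, str]:
        """Reference-derived transcript sequences (one per annotated gene)."""
        ref = _seq.encode(self.reference[CHROM])
        tlen = self.config.transcript_length
        out = {}
        for g in self.genes:
            codes = ref[g.start : g.start + tlen]
            if g.strand == "-":
                codes = _seq.revcomp_codes(codes)
            out[g.gene_id] = _seq.decode(codes)
        return out

    def site_transcript_coords(self) -> dict[str, list[tuple[str, int]]]:
        """Map transcript id -> [(site_id, 0-based offset within transcript)]."""
        tlen = self.config.transcript_length
        out: dict[str, list[tuple[str, int]]] = {}
        for site in self.sites:
            gene = next(
                g for g in self.genes
                if g.start <= site.pos - 1 < g.start + tlen
            )
            off = site.pos - 1 - gene.start
            if gene.strand == "-":
                off = tlen - 1 - off
            out.setdefault(gene.gene_id, []).append((site.site_id, off))
        return out


def _random_other(rng: np.random.Generator, code: int) -> int:
    return int((code + rng.integers(1, 4)) % 4)


def _diverge(rng: np.random.Generator, codes: np.ndarray, rate: float, skip: int) -> np.ndarray:
    """Substitute each position (except `skip`) with probability `rate`."""
    out = codes.copy()
    if rate > 0:
        mask = rng.random(len(codes)) < rate
        mask[skip] = False
        idx = np.flatnonzero(mask)
        out[idx] = (out[idx] + rng.integers(1, 4, size=len(idx))) % 4
    return out


def simulate_cohort(config: SimConfig) -> Cohort:
    """Build reference, individuals, planted sites and the truth table.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tlen = config.transcript_length

    n_par = int(round(config.paralog_fraction * config.n_genes))
    n_cnv = int(round(config.cnv_fraction * config.n_genes))
    n_units = config.n_genes + n_par
    gap = (config.genome_length - n_units * tlen) // (n_units + 1)
    if gap < 10:
        raise CohortSizingError(
            f"genome_length={config.genome_length} cannot hold {config.n_genes} genes "
            f"plus {n_par} paralog copies of length {tlen} without overlap"
        )
    if config.n_genes < n_par + n_cnv + config.n_true_edits:
        raise CohortSizingError(
            "not enough genes for the requested paralog/CNV/edit counts "
            "(one planted cause per gene)"
        )

    ref = rng.integers(0, 4, size=config.genome_length).astype(np.uint8)

    starts = [gap + i * (tlen + gap) for i in range(n_units)]
    width = len(str(config.n_genes))
    genes = [
        _Gene(f"g{i:0{width}d}", starts[i], "+-"[int(rng.integers(2))])
        for i in range(config.n_genes)
    ]
    paralog_slots = starts[config.n_genes :]

    # assign one planted cause per gene, disjointly
    order = rng.permutation(config.n_genes)
    par_genes = [genes[i] for i in order[:n_par]]
    n_poly = int(round(config.polymorphic_paralog_fraction * n_par))
    poly_set = {g.gene_id for g in par_genes[:n_poly]}
    cnv_genes = [genes[i] for i in order[n_par : n_par + n_cnv]]
    edit_genes = [genes[i] for i in order[n_par + n_cnv : n_par + n_cnv + config.n_true_edits]]

    individuals = [f"ind{i:02d}" for i in range(config.n_individuals)]
    margin = min(tlen // 4, config.rna_read_length)

    sites: list[RddSite] = []
    truth: list[TruthRecord] = []
    ref_paralogs: dict[str, _ParalogCopy] = {}
    cnv_copies: dict[str, _ParalogCopy] = {}
    edit_sites: dict[str, list[tuple[str, int, int]]] = {}
    forced_snps: list[tuple[str, int, int, int]] = []  # (individual, hap, pos0, alt_code)
    cnv_alleles: dict[str, dict[str, int]] = {}
    special_positions: set[int] = set()

    def trap_position(gene: _Gene) -> int:
        return int(gene.start + rng.integers(margin, tlen - margin))

    def tx_base(code: int, strand: str) -> str:
        b = _seq.BASES[code]
        return b if strand == "+" else _seq.revcomp(b)

    def add_site(gene: _Gene, pos0: int, b_tx: str) -> RddSite:
        a_tx = tx_base(int(ref[pos0]), gene.strand)
        site = RddSite(f"s{len(sites):04d}", CHROM, pos0 + 1, gene.strand, a_tx, b_tx)
        sites.append(site)
        special_positions.add(pos0)
        return site

    def pick_carriers(p: float) -> list[str]:
        carriers = [ind for ind in individuals if rng.random() < p]
        if not carriers:
            carriers = [individuals[int(rng.integers(config.n_individuals))]]
        return carriers

    # --- reference paralogs (matching and polymorphic) -----------------------
    for slot, gene in zip(paralog_slots, par_genes):
        pos0 = trap_position(gene)
        trap_off = pos0 - gene.start
        a_code = int(ref[pos0])
        b_code = _random_other(rng, a_code)
        copy = _diverge(rng, ref[gene.start : gene.start + tlen], config.paralog_divergence, trap_off)
        polymorphic = gene.gene_id in poly_set
        if not polymorphic:
            copy[trap_off] = b_code  # reference copy shows the RDD nucleotide
        forward = bool(rng.integers(2))
        inserted = copy if forward else _seq.revcomp_codes(copy)
        ins_trap = trap_off if forward else tlen - 1 - trap_off
        ref[slot : slot + tlen] = inserted
        pc = _ParalogCopy(gene.gene_id, slot, forward, inserted, ins_trap)
        ref_paralogs[gene.gene_id] = pc
        special_positions.add(slot + ins_trap)

        b_tx = tx_base(b_code, gene.strand)
        site = add_site(gene, pos0, b_tx)
        donor = f"{CHROM}:{slot + ins_trap + 1}"
        if polymorphic:
            # carriers get a het SNP at the copy's trap turning it into the RDD state
            alt = b_code if forward else int(_seq.comp_codes(np.array([b_code], dtype=np.uint8))[0])
            carriers = pick_carriers(config.paralog_snp_freq)
            for ind in carriers:
                forced_snps.append((ind, int(rng.integers(2)), slot + ins_trap, alt))
            truth.append(TruthRecord(site.site_id, "polymorphic_paralog", donor, frozenset(carriers)))
        else:
            truth.append(TruthRecord(site.site_id, "ref_paralog", donor, frozenset(individuals)))

    # --- segregating duplications (absent from the reference) ----------------
    for gene in cnv_genes:
        pos0 = trap_position(gene)
        trap_off = pos0 - gene.start
        a_code = int(ref[pos0])
        b_code = _random_other(rng, a_code)
        copy = _diverge(rng, ref[gene.start : gene.start + tlen], config.paralog_divergence, trap_off)
        copy[trap_off] = b_code
        cnv_copies[gene.gene_id] = _ParalogCopy(gene.gene_id, -1, True, copy, trap_off)

        alleles = {
            ind: int(np.sum(rng.random(2) < config.cnv_allele_freq)) for ind in individuals
        }
        if not any(alleles.values()):
            alleles[individuals[int(rng.integers(config.n_individuals))]] = 1
        cnv_alleles[gene.gene_id] = alleles
        carriers = frozenset(ind for ind, k in alleles.items() if k > 0)

        site = add_site(gene, pos0, tx_base(b_code, gene.strand))
        # a segregating copy has no reference coordinate; record the parent trap
        truth.append(TruthRecord(site.site_id, "cnv_paralog", f"{CHROM}:{pos0 + 1}", carriers))

    # --- true editing events -------------------------------------------------
    for gene in edit_genes:
        pos0 = trap_position(gene)
        if config.edit_substitution is not None:
            a_tx, b_tx = config.edit_substitution.split(">")
            # rewrite the reference base so the transcript shows the requested A
            a_genomic = a_tx if gene.strand == "+" else _seq.revcomp(a_tx)
            ref[pos0] = _seq.BASES.index(a_genomic)
            b_genomic = b_tx if gene.strand == "+" else _seq.revcomp(b_tx)
            b_code = _seq.BASES.index(b_genomic)
        else:
            b_code = _random_other(rng, int(ref[pos0]))
        site = add_site(gene, pos0, tx_base(b_code, gene.strand))
        tx_off = pos0 - gene.start if gene.strand == "+" else tlen - 1 - (pos0 - gene.start)
        b_tx_code = b_code if gene.strand == "+" else int(_seq.comp_codes(np.array([b_code], dtype=np.uint8))[0])
        edit_sites.setdefault(gene.gene_id, []).append((site.site_id, tx_off, b_tx_code))
        truth.append(TruthRecord(site.site_id, "true_edit", None, frozenset(individuals)))

    # --- background heterozygosity ------------------------------------------
    snps: dict[str, tuple[dict[int, int], dict[int, int]]] = {}
    for ind in individuals:
        hap_snps: tuple[dict[int, int], dict[int, int]] = ({}, {})
        if config.snp_rate > 0:
            positions = np.flatnonzero(rng.random(config.genome_length) < config.snp_rate)
            haps = rng.integers(0, 2, size=len(positions))
            offs = rng.integers(1, 4, size=len(positions))
            for p, h, o in zip(positions, haps, offs):
                if int(p) in special_positions:
                    continue
                hap_snps[int(h)][int(p)] = int((ref[p] + o) % 4)
        snps[ind] = hap_snps
    for ind, hap, pos0, alt in forced_snps:
        snps[ind][hap][pos0] = alt

    gene_intervals = [Interval(CHROM, g.start, g.start + tlen, g.gene_id) for g in genes]
    transcribed = list(gene_intervals)
    if config.paralogs_transcribed:
        transcribed += [
            Interval(CHROM, pc.start, pc.start + tlen, f"{gid}_par")
            for gid, pc in sorted(ref_paralogs.items())
        ]
    dup_intervals = [
        Interval(CHROM, g.start, g.start + tlen, g.gene_id) for g in cnv_genes
    ]

    return Cohort(
        config=config,
        reference={CHROM: _seq.decode(ref)},
        sites=sites,
        truth=truth,
        individuals=individuals,
        genes=genes,
        gene_intervals=gene_intervals,
        transcribed_intervals=transcribed,
        dup_intervals=dup_intervals,
        snps=snps,
        cnv_alleles=cnv_alleles,
        ref_paralogs=ref_paralogs,
        cnv_copies=cnv_copies,
        edit_sites=edit_sites,
    )


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SourceSeq:
    """One sequence in a sampling pool; weight scales its sampling density."""

    source_id: str
    codes: np.ndarray
    weight: float = 1.0


@dataclasses.dataclass
class ReadSet:
    """Fixed-length reads as an encoded matrix, ids carrying provenance."""

    ids: list[str]
    codes: np.ndarray  # (n_reads, read_length) uint8

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for rid, row in zip(self.ids, self.codes):
            yield rid, _seq.decode(row)


def simulate_reads(
    sources: Sequence[SourceSeq],
    depth: float,
    read_length: int,
    error_rate: float,
    seed: int | np.random.Generator,
) -> ReadSet:
    """Uniform single-end reads from a weighted pool of source sequences.

    A source of length L and weight w receives on average ``depth * w`` fold
    coverage at interior positions.  Per-base errors substitute a uniformly
    chosen different nucleotide.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sources = [s for s in sources if len(s.codes) >= read_length and s.weight > 0]
    if not sources:
        return ReadSet([], np.empty((0, read_length), dtype=np.uint8))

    eff = np.array([(len(s.codes) - read_length + 1) * s.weight for s in sources])
    n_reads = int(round(depth * sum(len(s.codes) * s.weight for s in sources) / read_length))
    counts = rng.multinomial(n_reads, eff / eff.sum()) if n_reads > 0 else np.zeros(len(sources), int)

    ids: list[str] = []
    blocks: list[np.ndarray] = []
    serial = 0
    for src, k in zip(sources, counts):
        if k == 0:
            continue
        starts = rng.integers(0, len(src.codes) - read_length + 1, size=k)
        win = np.lib.stride_tricks.sliding_window_view(src.codes, read_length)
        blocks.append(win[starts].copy())
        ids.extend(f"{src.source_id}:{s}:{serial + i}" for i, s in enumerate(starts))
        serial += int(k)
    codes = np.vstack(blocks) if blocks else np.empty((0, read_length), dtype=np.uint8)

    if error_rate > 0 and codes.size:
        mask = rng.random(codes.shape) < error_rate
        mask &= codes < 4
        offs = rng.integers(1, 4, size=int(mask.sum()))
        codes[mask] = (codes[mask] + offs) % 4
    return ReadSet(ids, codes)


def _haplotype(cohort: Cohort, individual: str, hap: int) -> np.ndarray:
    codes = _seq.encode(cohort.reference[CHROM]).copy()
    for pos0, alt in cohort.snps[individual][hap].items():
        codes[pos0] = alt
    return codes


def dna_read_pool(cohort: Cohort, individual: str) -> list[SourceSeq]:
    """Two genome haplotypes plus any duplication copies the individual carries.

    Weights are per-haploid-copy; pass ``depth/2`` to `simulate_reads` for a
    diploid-locus coverage of ``depth``.
    """
    pool = [
        SourceSeq(f"{individual}|hap0", _haplotype(cohort, individual, 0)),
        SourceSeq(f"{individual}|hap1", _haplotype(cohort, individual, 1)),
    ]
    for gid, copy in sorted(cohort.cnv_copies.items()):
        k = cohort.cnv_alleles[gid].get(individual, 0)
        for a in range(k):
            pool.append(SourceSeq(f"{individual}|{gid}|cnv{a}", copy.codes))
    return pool


def rna_read_pool(cohort: Cohort, individual: str) -> list[SourceSeq]:
    """Per-haplotype transcripts of annotated genes, transcribed paralog copies,
    duplication copies, and edited transcript variants."""
    cfg = cohort.config
    tlen = cfg.transcript_length
    pool: list[SourceSeq] = []

    hap_codes = [_haplotype(cohort, individual, h) for h in (0, 1)]

    def oriented(codes: np.ndarray, strand: str) -> np.ndarray:
        return codes if strand == "+" else _seq.revcomp_codes(codes)

    for gene in cohort.genes:
        for h in (0, 1):
            tx = oriented(hap_codes[h][gene.start : gene.start + tlen], gene.strand)
            edits = cohort.edit_sites.get(gene.gene_id)
            base_id = f"{gene.gene_id}|hap{h}"
            if edits:
                edited = tx.copy()
                for _sid, off, b_code in edits:
                    edited[off] = b_code
                pool.append(SourceSeq(f"{base_id}|tx", tx, 1.0 - cfg.edit_fraction))
                pool.append(SourceSeq(f"{base_id}|edit", edited, cfg.edit_fraction))
            else:
                pool.append(SourceSeq(f"{base_id}|tx", tx))

    if cfg.paralogs_transcribed:
        for gid, pc in sorted(cohort.ref_paralogs.items()):
            gene = next(g for g in cohort.genes if g.gene_id == gid)
            # transcription strand chosen so the copy's transcript matches the
            # parent gene's transcript frame
            tx_strand = gene.strand if pc.forward else ("-" if gene.strand == "+" else "+")
            for h in (0, 1):
                tx = oriented(hap_codes[h][pc.start : pc.start + tlen], tx_strand)
                pool.append(SourceSeq(f"{gid}|par|hap{h}", tx))

    for gid, copy in sorted(cohort.cnv_copies.items()):
        k = cohort.cnv_alleles[gid].get(individual, 0)
        if k:
            gene = next(g for g in cohort.genes if g.gene_id == gid)
            tx = oriented(copy.codes, gene.strand)
            pool.append(SourceSeq(f"{gid}|cnvtx", tx, float(k)))
    return pool


def simulate_dna_reads(cohort: Cohort, individual: str, seed: int | np.random.Generator) -> ReadSet:
    cfg = cohort.config
    return simulate_reads(
        dna_read_pool(cohort, individual), cfg.dna_depth / 2.0,
        cfg.rna_read_length, cfg.error_rate, seed,
    )


def simulate_rna_reads(cohort: Cohort, individual: str, seed: int | np.random.Generator) -> ReadSet:
    cfg = cohort.config
    return simulate_reads(
        rna_read_pool(cohort, individual), cfg.rna_depth / 2.0,
        cfg.rna_read_length, cfg.error_rate, seed,
    )
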