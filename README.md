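# rddaudit

Audit pipeline for claimed RNA–DNA difference (RDD) sites. Given a reference
genome, a candidate-site table, and RNA/DNA short reads per individual, it
asks whether each claimed difference has a mundane genomic explanation instead
of RNA editing:

* the reference genome itself already shows the "RNA" nucleotide at the site
  (reference-mismatch sites);
* a reference paralog of the gene carries the RNA nucleotide, so accurate
  transcription of the paralog mimics editing (49-bp flank queries searched
  genome-wide, hits kept at >90% identity and ≥50 bp);
* the individual's own genomic reads show the RNA nucleotide (lenient: ≥1
  read; stringent: ≥90% of reads show A or B and ≥10% of those show B, with
  no minimum coverage), after mapping with ≤5 mismatches and discarding reads
  with more than one non-site mismatch;
* the site or its paralogs fall in copy-number-variable regions (reported and
  tested for enrichment by a random-position permutation test, but not counted
  as per-site proof).

RDD calling from RNA pileups uses the standard three criteria (≥10 reads,
≥90% A/B, ≥10% B among A/B) evaluated with exact rational arithmetic, and a
nucleotide-swap control quantifies how often the stringent criterion passes by
sequencing error alone. A rarefaction module tracks sites eliminated as
individuals' genomic data are added in random order and extrapolates the curve
with a saturation fit.

Because the original external resources (site tables, reference builds, cohort
reads, annotation releases) are not bundled, the package ships a first-class
synthetic-data module: it plants reference paralogs, polymorphic paralogs,
segregating duplications, and true editing events with known ground truth so
the whole audit is testable end to end, including sensitivity/specificity
scoring of the final "explained" verdict.

## Layout

| module | role |
| --- | --- |
| `rddaudit.simulate` | synthetic cohorts (genome, diploid individuals, transcripts, reads, truth table) |
| `rddaudit.align` | flank database, desk-scale exact ungapped read mapper, mismatch filters, pileups, SAM interchange |
| `rddaudit.calling` | the three RDD-calling criteria, per-individual and cohort summaries |
| `rddaudit.paralog` | genome-wide flank search, hit classification and gene/transcribed annotation, PSL/BLAST readers |
| `rddaudit.evidence` | lenient/stringent genomic-read verdicts, any-individual aggregation, swap control, match rates |
| `rddaudit.stats` | exact Fisher tests, A→G composition shift, CNV-overlap permutation test |
| `rddaudit.rarefaction` | elimination curves, saturation fits, extrapolation |
| `rddaudit.pipeline` | orchestration, consolidated verdict table, truth scoring, YAML-configured runs |
| `rddaudit.cli` | `rddaudit` command with per-stage subcommands |

The in-package mapper and flank search are exact (pigeonhole-seeded) stand-ins
for a short-read mapper and BLAT: they reproduce an exhaustive Hamming-window
scan at desk scale, and SAM/PSL/BLAST-tabular readers let real tools be
substituted at the alignment/hit level.

## CLI

```
rddaudit simulate --seed 3 --out cohort/            # synthetic cohort + reads
rddaudit map --reads cohort/reads/ind00.dna.fastq \
    --sites cohort/sites.tsv --reference cohort/reference.fasta --out ind00.sam
rddaudit screen --sites cohort/sites.tsv --reference cohort/reference.fasta \
    --genes cohort/genes.bed --transcribed cohort/transcribed.bed --out hits.tsv
rddaudit run --config run.yaml                       # full pipeline
rddaudit score --verdicts run/verdicts.tsv --truth cohort/truth.tsv
```

A `run.yaml` holds an `outdir`, a master `seed`, a `sim:` block (SimConfig
fields) and a `params:` block (AuditParams fields); every threshold defaults
to the published values. Outputs land under the run directory: verdict table,
calls, pileups, paralog hits, rarefaction curve, and a `report.json` with the
swap control, match rates, A→G shift, permutation test and saturation fit.

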