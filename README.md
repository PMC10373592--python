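# ampledit

Analysis toolkit for multi-allelic CRISPR/Cas9 editing outcomes in
polyploid amplicon deep-sequencing data, with a ground-truthed read
simulator for end-to-end validation.

The pipeline covers:

- **`ampledit.locus`** — the amplicon locus model: haplotypes defined by SNP
  profiles at variable positions, sgRNA target sites (protospacer + NGG PAM,
  blunt cut 3 nt 5' of the PAM), primers and restriction enzymes; in-silico
  PCR and CAPS digestion.
- **`ampledit.calling`** — indicator-pair read filtering and alignment-based
  indel calling per target (comparison range `R`, WT marker `r`, minimum
  pattern frequency `n`), with left-normalised indels, frameshift
  classification (net indel not a multiple of three), dropout-deletion
  detection, and per-site summaries.
- **`ampledit.variants`** — exact-match tracking of catalogued native
  target-region variants (protospacer/PAM SNPs and small indels) and
  line-vs-background enrichment deltas.
- **`ampledit.alleles`** — haplotype assignment of clone reads by SNP
  profile, detection of homology-directed-repair (HDR) recombinants as
  donor-genotype reads on a foreign haplotype backbone, conversion-tract
  bounding from flanking SNPs, and the background-corrected HDR frequency
  estimate.
- **`ampledit.ce`** — capillary-electrophoresis peak-table genotyping:
  WT/mutant peak classification, peak-height mutation frequency, and
  chimerism assessment across subsamples.
- **`ampledit.report`** — transformation/editing/uniformity/progeny-recovery
  rates, percent reductions, one-way ANOVA with balanced Tukey HSD and a
  compact letter display, and TSV table rendering.
- **`ampledit.simulate`** — the synthetic-data generator: a 586 bp two-target
  demonstration locus (15 haplotypes over 36 variable positions, one
  haplotype uneditable at both targets), edited cell-lineage mixtures with
  NHEJ indels, ~100 bp dropout deletions, HDR conversion tracts and
  sequencing error, emitting FASTQ/FASTA pools, CE peak tables and per-read
  ground truth.

## Command line

```bash
ampledit demo-locus --seed 1 --out locus/            # write the demo locus
ampledit simulate --locus locus/locus.json --seed 5 \
    --reads 10000 --cut-prob 0.7 --out sim/          # simulate a pool
ampledit call --locus locus/locus.json --reads sim/reads.fastq \
    --target sgRNA2 --R 30 --r 5 --n 1 --out sim/calls.tsv
ampledit variants --locus locus/locus.json --reads sim/reads.fastq \
    --target sgRNA2 --catalog catalog.tsv
ampledit ce --peaks peaks.tsv --wt-size 216
ampledit report --tallies tallies.tsv --spad spad.tsv --out reports/
```

Locus configuration is a directory with a JSON manifest pointing at a
single-record FASTA reference and TSV tables for haplotypes
(`hap_id position base`), targets (`id protospacer pam strand`), primers
and enzymes; `ampledit.locus.save_locus` writes one.

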