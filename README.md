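# cnvpol

Consensus CNV discovery, ancestral-state polarization, and
formation-mechanism classification for population resequencing panels —
exercised end-to-end on synthetic rice-like genomes with mechanism-labelled
implanted variants.

## The problem

Short-read surveys of a population against one reference genome yield, per
accession, deletion calls from three complementary evidence classes:
paired-end discordance (PE), split-read alignment (SR) and read depth (RD).
Turning those into a usable catalog of copy number variants (CNVs, events
≥ 50 bp) requires answering four questions this package implements:

1. **Which calls are real?** Per accession, calls supported by ≥ 2 callers
   under a stringent 50% reciprocal-overlap criterion are kept, their
   breakpoints refined by evidence priority (SR junctions are
   single-nucleotide), and events observed in ≥ 3 accessions form the
   population catalog (`cnvpol.merge`).
2. **Deletion or insertion?** A "deletion relative to the reference" may
   really be an insertion acquired by the reference lineage. Each event is
   projected onto an outgroup genome through co-linear blocks of ortholog
   anchors and its sequence ± 2 kb flanks aligned to the projected window;
   the flank-to-flank span in the outgroup decides
   insertion / deletion / undefined (`cnvpol.polarize`).
3. **What made it?** Breakpoint junction signatures classify each event's
   formation mechanism: VNTR (integer period change inside a tandem
   array), MEI (a transposable-element body with target-site duplication),
   NAHR (≥ 50 bp of ≥ 90%-identity junction homology), NHR (blunt/NHEJ or
   1–10 bp microhomology/MMEJ junctions), else ambiguous
   (`cnvpol.mechanism`).
4. **What does it hit, and where did CNV genes come from?** Gene-model
   overlap categories (full / partial-CDS / UTR / intron), population
   sharing between cultivated and wild accessions, hypergeometric term
   enrichment with BH-FDR (`cnvpol.impact`); and for CNV genes at
   non-co-linear positions, a genome-wide seed-and-extend homolog search
   plus breakpoint context infers the duplication origin — TE capture,
   NHEJ, or NAHR (`cnvpol.noncolinear`).

Real caller outputs are not required: `cnvpol.sim` generates a reference
genome with annotated TEs, tandem arrays and gene models, implants
mechanism-labelled events with exact ground truth, derives a diverged
outgroup with assembly gaps from the ancestral haplotype, and emulates the
three callers' sensitivity, breakpoint noise and false calls. Every
pipeline guarantee is stated and tested against this truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
panel (160 events + 12 gene duplications, 12 accessions, 2 × 1 Mb
chromosomes, 2% outgroup divergence, noisy callers):

```bash
python analysis/01_simulate.py
python analysis/02_merge_calls.py
...
python analysis/07_report.py
```

The final report (also in `results/report.txt`) prints:

```
CNV catalog: 156 consensus deletion events
  size mean 2724 bp, median 1156 bp, range 75-30019 bp
  single-nucleotide breakpoints: 100.0%
polarity (vs. outgroup):
  deletion: 27 (17.3%, 27/156)
  insertion: 127 (81.4%, 127/156)
  undefined: 2 (1.3%, 2/156)
formation mechanisms:
  MEI: 40 (25.64%), 109151 bp cumulative
  NAHR: 38 (24.36%), 88630 bp cumulative
  NHR: 50 (32.05%), 224009 bp cumulative
  VNTR: 28 (17.95%), 3204 bp cumulative
gene impact: 70 genes affected by 67 CNVs (full 29, partial CDS 39, UTR 2, intron 0)
sharing [cultivated_wild]: cultivated_only 21.8%, shared 78.2%
sharing [indica_japonica]: indica_only 7.7%, japonica_only 5.1%, shared 87.2%
non-co-linear CNV genes: 38/70; origins {'TE': 10, 'NHEJ': 6, 'NAHR': 1}
```

Reading it: the merge recovered 156 of 172 implanted events (recall 0.91,
precision 1.00 — script 02 prints these), all at single-nucleotide
resolution; 81.4% of events polarize as reference-lineage insertions,
matching the simulated 80% insertion fraction; the mechanism distribution
re-derives the implanted 40-per-class design (plus the NHR-flanked gene
duplications); and 11 of the 12 implanted duplications get the correct
TE/NHEJ/NAHR origin call (script 06).

The same stages are available as a CLI for arbitrary datasets in the same
formats:

```bash
cnvpol simulate --out data --seed 42
cnvpol merge --calls data --out run
cnvpol polarize --data data --out run
cnvpol mechanism --data data --out run
cnvpol impact --data data --out run
cnvpol origin --data data --out run
cnvpol report --out run          # or: cnvpol all --config run.yaml
```

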