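# fruitmir

Discovery and validation of microRNAs from fruit small-RNA sequencing
libraries: read cleaning and accounting, an ncRNA annotation cascade,
known-miRNA assignment with cross-species conservation, hairpin-based
novel-miRNA prediction, plant-style target prediction, degradome
cleavage-site validation, and 2^-ΔΔCt relative quantification.

## Who this is for

Plant small-RNA analysts who want a transparent, testable implementation
of the classic deep-sequencing miRNA discovery workflow — the kind run on
fruit tissue libraries of ~17 M Illumina reads against a draft genome and
a miRBase mature set — together with a synthetic-data generator that
plants known ground truth (hairpins, target sites, cleavage positions,
fold changes) so every stage can be checked for exact recovery.

## The analysis

**Read cleaning.** Raw reads are assigned to exactly one category in a
fixed order (low quality → 3′-adaptor null → insert null → 5′-adaptor
contaminant → shorter than 18 nt → poly(A) → clean), so the accounting
identity `clean = high_quality − Σ removed` holds on any input. Clean
reads are collapsed into unique *tags* with redundant counts.

**Annotation cascade.** Tags are mapped exactly to the genome on both
strands and classified by precedence
(miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > exon > intron >
unannotated); exon/intron split into sense/antisense by strand. The
unannotated pool feeds novel-miRNA prediction.

**Novel miRNAs.** Read loci are excised with genomic flanks, folded with
ViennaRNA, and the miRNA/miRNA\* duplex (star inferred by the 2-nt 3′
overhang rule) must satisfy nine criteria: mature length 18–25 nt,
reference-locus span 20–23 nt, ≤ 20 genomic copies, precursor MFE ≤ −18
kcal/mol, miRNA–miRNA\* spacing ≤ 300 nt, ≥ 16 base pairs, bulges ≤ 4 nt,
duplex asymmetry ≤ 4 nt, and ≥ 20 nt precursor flank — plus a ≥ 5-read
expression floor.

**Targets.** Transcript windows are scored against each miRNA with
antiparallel position-wise states (Watson–Crick / G:U wobble / mismatch;
a wobble counts 0.5 mismatches) under six rules: total score ≤ 4; no
mismatch run > 2; no adjacent mismatches at positions 2–12; no mismatch
at positions 10–11; score ≤ 2.5 over positions 1–12; duplex MFE ≥ 75% of
the perfect-duplex MFE.

**Degradome validation.** Degradome read 5′ ends build a per-transcript
density; a predicted site at transcript coordinates [s, e] is validated
when a peak sits at `e − 9`, the position pairing miRNA nucleotide 10
(the canonical cut between nucleotides 10 and 11). Peaks get categories
0–4 (unique maximum … singleton).

**Expression.** 2^-ΔΔCt with per-replicate ΔCt, replicate SE propagated
by the delta method.

## Worked example

Run the whole pipeline on a bundled synthetic dataset (four 30-kb
scaffolds, 10 planted true hairpins, 9 decoys each violating one
criterion, 50 000 reads):

```bash
fruitmir run --outdir demo --seed 1
```

which prints `pipeline complete; stages: [...]` and writes, among others,
`demo/filter_summary.tsv`:

```
type                  count   percentage
total_reads           50000
high_quality          49902   100.00
adaptor3_null            19     0.04
insert_null              15     0.03
adaptor5_contaminant     96     0.19
shorter_than_min       1155     2.31
polyA                     0     0.00
clean_reads           48617    97.42
```

(the five removal categories partition the high-quality reads; the
percentages are relative to the high-quality total) and
`demo/novel_mirnas.tsv` with exactly the ten planted true hairpins:

```
id     scaffold    start  end    strand  mfe    mature                 star                   read_count
m0001  scaffold_1  4302   4400   +       -37.8  TCAAAGTACACGGTAGCGGTC  CCGCTACCGTGTACTTTGAAC  33
m0002  scaffold_1  12931  13029  +       -39.1  TGGGATACCGGCGAGATAGTA  CTATCTCGCCGGTATCCCAAA  26
...                                      (10 rows)
```

`demo/cleavage_events.tsv` lists the degradome-validated sites with their
cleavage position (site end − 9) and peak category, and
`demo/expression.tsv` the per-stage 2^-ΔΔCt values with the calibrator at
1.0.

The same stages are available individually (`fruitmir simulate |
preprocess | annotate | known | novel | targets | degradome | quantify`)
and as library functions (`fruitmir.preprocess.filter_reads`,
`fruitmir.novel.predict_novel`, `fruitmir.targets.scan_transcriptome`, …).

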