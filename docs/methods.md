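# Methods

This note documents the models and procedures behind each stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Read cleaning and accounting

Reads are classified into exactly one category, tested in a fixed order:
low quality, 3′-adaptor null, insert null, 5′-adaptor contaminant,
shorter than the minimum insert, poly(A), clean. Because the order is
fixed and every read lands in one bucket, the accounting identity
`clean = high_quality − Σ removed` is structural, not empirical, and is
fuzz-tested on arbitrary input.

Definitions the source workflow names but does not define are frozen here
as the standard Illumina small-RNA conventions and are configurable:

* *low quality*: mean Phred < 20 or > 10% N calls;
* *3′ adaptor null*: no occurrence of the first 6 nt of the 3′ adapter
  (a trimmed insert longer than the 30-nt size-selection window is
  treated the same way — the apparent adapter hit is spurious);
* *insert null*: adapter at read position 0;
* *5′ adaptor contaminant*: insert begins with ≥ 8 nt of the 5′ adapter;
* *poly(A)*: ≥ 80% A after trimming.

Percentages are reported against the high-quality total to two decimals
with half-up rounding, matching the way such accounting tables are
printed.

## Annotation cascade

Tags map to the genome by exact substring search on both strands (a
12-mer seed index, then full verification). Classification uses a
precedence order — miRNA, rRNA, tRNA, snRNA, snoRNA, repeat, exon,
intron, unannotated — with ≥ 1 nt feature overlap sufficing and
exon/intron refined to sense/antisense by strand comparison. Known-miRNA
membership is a sequence test (containment alignment, ≤ 1 substitution by
default) against the mature reference set, so it does not depend on the
miRNA loci being present in the (draft) genome. Tags with no hit and no
category are unannotated-and-unmapped; keeping them in the summary makes
the category table partition the tag set exactly.

## Known miRNAs and conservation

Tag-to-mature alignment allows substitutions only, no indels, with the
shorter sequence fully contained in the longer (isomiR-style length
offsets are free; the default limit is 2 substitutions). Each tag gets
one best hit, ties broken by miRNA id, so counts are never double-booked
and the result is order-invariant. Families are the `miR` + leading
integer convention (ppe-miR156a → miR156). Conservation states per family
and species are: *identical* (some member tag exactly equals a mature of
that species), *variant* (within the substitution limit), *absent* —
rendered `++` / `+` / blank.

## Novel-miRNA prediction

Unannotated tag hits are clustered per scaffold and strand (gap ≤ 200
nt). For each locus the dominant (highest-count) tag is the mature
candidate. Excision tries both arm orientations with a fixed extension
ladder (80/160/260/380 nt beyond the tag, 40 nt behind it), folds each
window (ViennaRNA MFE structure), and keeps the window pairing the most
mature bases (ties: smaller window); the ladder stops early once 16
mature bases pair. The chosen window is trimmed to the duplex span plus a
20-nt flank and refolded; that trimmed precursor is what the criteria
see. The 380-nt rung exists so precursors with loops beyond the 300-nt
bound are still excisable — and can then fail on the spacing criterion
rather than never being built.

The miRNA\* is the pairing partner of the mature arm shifted 2 nt toward
its 3′ end (the canonical Dicer 2-nt 3′ overhang). Duplex geometry is
read off the pair table: `paired_bases` counts mature positions paired
outside the mature region; `max_bulge` is the longest unpaired run
interior to the duplex on either strand; `asymmetry` is the absolute
difference of interior unpaired totals; `loop_space` is the gap between
the mature region and the star-side partner span.

The nine criteria (defaults): mature length 18–25 nt; reference span
20–23 nt; ≤ 20 genomic copies of the mature tag; precursor MFE ≤ −18
kcal/mol; loop space ≤ 300 nt; ≥ 16 paired bases; bulge ≤ 4 nt; asymmetry
≤ 4 nt; flank ≥ 20 nt on both sides. A tenth, expression, filter requires
≥ 5 reads for the mature tag (the observed sequencing-frequency floor of
published novel sets).

Two deliberately fixed interpretations:

* *Reference span.* "Reference miRNA length 20–23 nt" is read as the
  genomic span of the mature-arm read cluster — the union of tag
  alignments overlapping the dominant tag, restricted to tags of
  plausible mature length (18–25 nt, a module constant). This separates
  the per-tag length bound from the locus-definition bound, makes both
  independently violable, and keeps excision independent of the criteria
  thresholds (which is what makes threshold-tightening provably
  monotone).
* *Copy number.* "Copy number of reference miRNAs ≤ 20" is a
  repeat-likeness cap: a mature tag with more than 20 genomic loci is
  rejected wherever it lands.

Both phrasings are ambiguous in the source description; these readings
are frozen, tested, and configurable.

## Target prediction

Duplexes are ungapped and antiparallel: miRNA position *i* (numbered from
the miRNA 5′ end) faces transcript position `site_end − i + 1`. States
are WC, GU (wobble = 0.5 mismatches) or MM. Rules 1–5 are purely
positional and are evaluated for every window with a vectorised state
matrix; the energy rule 6 runs only on positional survivors. Energies are
two-sequence hybridisation MFEs (RNAduplex model, no intramolecular
structure); the ratio criterion compares the site duplex with the miRNA
bound to its exact complement, the standard MFE-ratio reading of the
otherwise circular "not less than 75% of the MFE of the miRNA bound to
its target". G:U wobbles do not form or extend "adjacent mismatch" runs
by default (they are matches for adjacency, half-mismatches for scoring);
a strict mode is available. An independent brute-force oracle —
per-offset, per-position re-implementation of all six rules — is kept in
the test suite and must agree exactly with the scanner.

## Degradome validation

Degradome reads are matched sense-only and exactly (cleavage fragments
are exact transcript substrings); multi-mapping reads count once per
occurrence (a fractional mode splits the weight instead). For a site
[s, e] with e pairing miRNA nucleotide 1, the expected cut is at
`e − 9` — the transcript position pairing nucleotide 10, i.e. the
position 5′-most in the downstream fragment when the duplex is cut
between nucleotides 10 and 11. Events are emitted per miRNA without
suppression, so identical-sequence miRNAs each claim a shared position.
Peak categories are the established degradome convention, frozen for
testability: 0 unique transcript maximum (> 1), 1 shared maximum (> 1),
2 above the transcript median, 3 at/below the median but > 1, 4
singleton. No peak p-values are computed.

## 2^-ΔΔCt

Per replicate, ΔCt = Ct(target) − Ct(reference), replicates paired by
index; ΔΔCt = mean ΔCt(sample) − mean ΔCt(calibrator); expression =
2^(−ΔΔCt). The replicate SE of ΔCt propagates to the expression scale by
the delta method (se = rel · ln 2 · se_ΔCt). Per-replicate ΔCt before
averaging matches the "±SE of each mean (n = 9)" presentation of qPCR
panels. No amplification-efficiency correction is applied.

## Synthetic data: what it emulates, and what it does not

The generator's defaults reproduce the statistical structure of a deep
fruit small-RNA library: contaminant fractions at the published
accounting rates (3′-adaptor null 0.04%, insert null 0.02%, 5′-adaptor
contaminants 0.18%, < 18 nt 2.26%, poly(A) trace); clean reads split
miRNA 21.9%, rRNA 14.1%, tRNA 4.4%, sn/snoRNA 0.1%, exon/intron
fragments 9.6%, unannotated 49.9%; read lengths peaked at 21 nt (38.0%)
with a 24-nt secondary mode (29.8%); a 5′-U bias of 0.8 on mature
miRNAs. Genome scale is desk-sized — four 30-kb scaffolds, 50 000 reads,
10 true hairpins, 9 decoys, 20 known matures, 12 × 1.2-kb transcripts —
chosen so the full chain runs in tens of seconds while every recovery
check stays exact.

Planted hairpins are built from a duplex plan (paired blocks, bulges,
internal loops) with non-pairing substitutions (A↔C-style) at designed
mismatch positions, pairing-poor {A,C} loops and margins, and are
verified by the prediction module itself: the cassette is inserted into
the scaffold, re-excised with the production excision code, folded, and
its criterion report checked against the intended pass/fail pattern,
retrying with fresh sequences until it verifies. Decoy geometry respects
the couplings between criteria: the weak-MFE decoy uses an A/U-only stem
(so pairing stays ≥ 16 while MFE > −18); the bulge decoy places one 5-nt
bulge per strand (net asymmetry 0); the asymmetry decoy uses 3+2-nt
star-side bulges (no run > 4); the flank decoy sits at a scaffold edge.
Target sites are planted per rule label the same way (the label is
whatever the rule checker says about the constructed site), and the
emitted transcriptome is exhaustively rescanned to confirm no unplanted
passing site exists. Degradome reads pile up at the planted cut with
Poisson background.

Not emulated: sequencing errors and realistic quality strings (qualities
are constant Q40 except the low-quality class), isomiR ladders beyond
the deliberately planted offset tags, repeat-family structure (repeats
are consumed as annotation), RNA-editing, multi-library designs, and
real-genome scale. Passing the recovery tests therefore demonstrates the
pipeline's logic is correct under its stated assumptions — exact
matching, clean adapter ligation, planted structure — not its robustness
to sequencing noise or to genomes with pervasive repeats.

## Numerical and degenerate-input choices

Folding is deterministic (single-threaded ViennaRNA, default
parameters); MFEs are reported to 0.01 kcal/mol. Dominant-tag ties break
lexicographically; best-hit ties break to the smallest miRNA id; window
ties to the smaller window. Candidates whose mature region pairs nowhere
outside itself are rejected as duplex-undefined. Windows clipped at
scaffold edges are kept and simply measure a short flank. Degenerate
inputs (empty read sets, zero depth, empty densities, all-zero reports)
return valid empty results rather than erroring, except where the input
is structurally wrong (malformed FASTQ records, empty reference sets,
coordinates outside transcripts), which raise with context.

## Known limitations

Bounded-mismatch genome mapping is exhaustive-scan only (meant for small
synthetic genomes); the exact mapper is the production path. Target
prediction allows no target-side bulges (the six rules are purely
positional; this is stricter than bulge-tolerant scanners). Peak calling
uses a hard position match with no statistical model of background.
Hairpin excision evaluates one candidate per read locus (the dominant
tag), so antisense or minor-arm products at the same locus are not
emitted separately.
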