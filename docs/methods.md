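# Methods

## Model

The package treats translation calling as a drug-contrast problem. Each
footprint profile is a per-nucleotide count vector of ribosome P-sites on a
spliced transcript for one (condition, replicate) sample; conditions are a
whole-transcriptome RNA-seq control, an untreated footprint control, and
three inhibitor treatments (DMDA-pateamine A, which blocks initiation
upstream of scanning via eIF4A; harringtonine, an elongation inhibitor;
puromycin, a chain-terminating aminoacyl-tRNA mimic). The core assumption is
that footprints produced by translating ribosomes are depleted by the
inhibitors — most strongly and most uniformly by DMDA-PatA — while
non-translational RNase-resistant fragments (structure- or
protein-protected) are not. The per-ORF drug-resistant fraction
`drug / control` on spike-in-normalized counts is therefore the primary
translation statistic; the computational coding scores (TE, RR, ORFscore,
FLOSS, Kozak context) are computed alongside it for benchmarking.

Comparability across conditions rests entirely on the spike-in: a synthetic
RNA added at fixed mass to every footprint sample. Size factors that
equalize the spike counts make drug/control ratios independent of sequencing
depth. Whole-transcriptome replicates are instead normalized to each other
by median-of-ratios over all transcripts — two deliberately different
normalizations, because drug treatment changes the total footprint yield
(the thing being measured) but not the transcriptome.

## Pipeline stages and numerical choices

**Read filtering.** A read is kept when it is 26–36 nt, uniquely mapped
(`NH` tag 1, not secondary/supplementary), has mapping quality ≥ 10 and no
mismatch at its 5' base (detected from the `MD` tag at either end,
depending on strand). Uniqueness and the MAPQ cutoff are enforced
independently even though many aligners make one imply the other.

**P-site calibration.** Reads are reduced to 5' start positions; a metagene
sums read starts around the CDS start codons of the (up to) 800 coding
transcripts with the highest ribosome density, stratified by read length.
Density means control footprints per CDS nucleotide — a per-nt measure so
long CDSs are not favored. Per length stratum the offset is found in two
steps: the largest upstream peak fixes it to ±1 nt (the start-codon pileup
is spread over start ±1, so the raw argmax is ambiguous by one), and among
the three candidate offsets the one maximizing the downstream
center-of-codon phase mass wins. Ties prefer the peak-implied offset, then
the smaller one. Strata with no upstream signal inherit the all-length
offset; an entirely flat metagene raises an error rather than guessing.
Offsets are always calibrated from the data at hand, never hard-coded.
After projection (`P-site = 5' end + offset`), reads that leave the
transcript are dropped and counted, so accepted = projected + dropped is an
enforced invariant. A stop-anchored metagene is available for QC; it plays
no role in calibration.

**Representative transcript.** One transcript per gene: annotated beats
predicted, coding beats noncoding, fully annotated CDS beats partial. After
that, if any candidate has ≥ 2 % of its CDS footprints on start ±1 nt, the
unique such candidate wins (ties: highest CDS footprint count); otherwise
the longest CDS. Remaining ties go to the longest transcript, then the
lexicographically smallest id — an explicit final tie-break so selection is
a pure function of its inputs.

**Scores.**

- ORF coordinates are 0-based, half-open, on the spliced transcript; GTF
  input is converted at the boundary and minus-strand transcripts are
  reverse-complemented once, so everything downstream is strand-free. ORF
  lengths include the stop codon (a 3-amino-acid uORF is 12 nt); this
  convention is applied to AUG, CUG and near-cognate ORFs alike.
- TE divides ORF footprints by transcriptome reads after scaling the
  transcriptome to the control footprint total.
- RR defaults to the coding-high orientation (reciprocal of the printed
  ratio-of-ratios) so that "higher = more coding-like" holds for every
  score in a table; the as-printed orientation is a flag. The 3'UTR window
  runs to the first downstream AUG in any frame (full-3'UTR dialect
  available). A +1 pseudocount on all four region counts is the default,
  because zero 3'UTR footprints are the norm for coding transcripts and
  dropping those rows would discard exactly the cleanest cases.
- ORFscore expects the codon-position mode on the center nucleotide, which
  is what this package's offset convention produces; users of other
  conventions must remap. Codons holding > 70 % of an ORF's footprints are
  excluded before the phase sums; an all-zero ORF scores 0 and is flagged
  rather than erroring.
- FLOSS uses read lengths 26–34 nt and a reference aggregated from
  annotated CDSs with ≥ 100 control footprints; the score is half the L1
  distance (total variation), so it is symmetric and bounded in [0, 1].
- The Kozak matrix covers positions −5…−1, +3, +4; the AUG contributes 0.
  Windows truncated by the transcript edge are padded with N (scored 0) and
  usable. The column-max bound of the matrix is 443.79.
- Fold inhibitions are censored at 1000× when the drug count is zero, so
  medians stay finite; a zero control count makes the ratio undefined (NaN)
  rather than infinite.
- Near-cognate coverage is computed as an expectation (3 × codon
  probability per position, by linearity over the three covering frames).
  As a coverage *probability* the true value is slightly lower because
  adjacent occurrences overlap; the test suite quantifies this by
  simulation. The expectation arithmetic is what is reported.

**Classification.** Threshold wording is applied literally: "at least" is
inclusive, "more than" exclusive. For lncRNAs, only transcripts with an ORF
carrying ≥ 20 transcriptome reads are classified at all; an ORF is
considered only when it holds ≥ 10 % of the transcript's footprints (a
qualifying condition applied before any other rule, so trailing minor peaks
never drive a call). Categories are evaluated in order: no ORF above TE 0.1
→ low density; none of those with ≥ 4 footprints → insufficient; any
remaining ORF blocked ≥ 4× by PatA (or ≥ 2× harringtonine, or both,
depending on the chosen criterion) → translated; otherwise not supported.
The stringent uORF selection requires ≥ 8 footprints on start ±1, ≥ 20 on
the ORF and ≥ 3× PatA inhibition, all inclusive.

The cross-quantile coding classification is intentionally asymmetric: a
coding RNA counts as coding when it beats the 90th percentile of the
noncoding reference scores, a noncoding RNA when it beats the 10th
percentile of the coding scores. With identical score distributions this
calls ~10 % of coding and ~90 % of noncoding RNAs coding — a property of
the rule itself (each group is measured against the other group's opposite
tail), checked by simulation in the tests.

**Expression-matched bootstrap.** lncRNA ORF transcriptome read counts are
split into 100 equal-occupancy (quantile) bins; each bootstrap sample draws
as many coding transcripts as there are lncRNA ORFs, bin-wise with
probabilities equal to the bin densities and uniformly within a bin. Coding
transcripts outside the lncRNA read-count range belong to no bin and are
never drawn; a populated bin with no coding candidate falls back to the
nearest populated bin (logged).

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions everything downstream is validated against:

| parameter | default | why |
|---|---|---|
| transcriptome reads/transcript (median) | coding 345, lncRNA 50, snoRNA 150 | log-normal (σ=1.0); lncRNAs are low-expressed |
| fold inhibition on CDS (median) | PatA 22×, harringtonine 8.7×, puromycin 6.3× | log-normal per ORF, σ=0.5, clipped at 1 |
| fold on translated uORFs / lncRNA ORFs (PatA) | 8.5× / 11.3× | uORFs and short CDSs are somewhat less inhibited |
| snoRNA folds | ~1× (σ=0.03) | bona fide noncoding footprints are drug-invariant |
| puromycin per-codon survival | 0.95 | fold attenuated by 1+(fold−1)(1−0.95ⁿ): chain termination accumulates with length, so short ORFs are weakly blocked |
| codon phasing | (0.2, 0.6, 0.2) | center-heavy, matching the offset convention |
| start pileup fraction | 0.15 (0.5 for the 10 % stalled-start ORFs) | start-codon accumulation is near-universal; extreme stalling exists |
| read lengths | 26–36 nt, peaked at 30 (translational); flat (background) | distinct length signatures give FLOSS something to detect |
| spike-in | 10 000 reads on a 300-nt pseudo transcript | identical true abundance; per-sample depth factors (log-normal, σ=0.15) are the only perturbation |
| background footprint rate | 0.005 per transcriptome read | non-translational RNase-resistant fragments, uniform along the transcript, drug-invariant |
| replicates | 2 per condition | downstream statistics use normalized replicate means |

Drug action is independent binomial thinning of the control counts with
probability 1/fold, per position and read length — the simplest model under
which resistant fractions are per-ORF ratios and empirical ratios converge
at binomial rates. The background rate is the one genuinely free parameter
(no quantitative model of structure-protected fragments exists to copy);
it must sit well below 1/fold on coding sequences, since the measured
resistant fraction is signal-plus-background and a large background would
make the configured folds unrecoverable by construction. 0.005 keeps the
background near 7 % of the PatA-resistant remainder.

Transcript geometry: coding transcripts get log-normal 5'UTR/CDS/3'UTR
lengths (medians 150/1200/400 nt) with planted AUG uORFs in 40 % and CUG
uORFs in a further 30 % of 5'UTRs (half of the AUG and 15 % of the CUG
uORFs translated, median 33 nt); lncRNAs (median 800 nt) carry one planted
AUG ORF under 200 codons, translated in one third of transcripts; snoRNAs
(130 nt) carry a short untranslated AUG ORF so per-ORF scoring has a
noncoding reference class. Planted ORFs contain no in-frame stops;
infeasible geometry (an ORF longer than its host region) fails loudly.
Bundles are written as transcript FASTA + synthetic-genome FASTA + GTF
(with one- and two-exon genes on both strands, so the splicing arithmetic
is exercised by a round trip) + profile TSV + truth TSV, and optionally a
transcript-space SAM whose reads sit `offset` nt upstream of their P-site.
Fixed seed implies byte-identical bundles.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence-dependent coverage bias and ligation
bias; rRNA or other contamination; color-space sequencing artifacts;
genome-space alignment and spliced-read liftover; overlapping uORFs
competing for the same footprints (each planted ORF owns its reads);
inhibitor kinetics beyond a single per-ORF fold; reinitiation and leaky
scanning; RNA-seq coverage bias (transcriptome reads are uniform). Recovery
results on synthetic data bound the pipeline's correctness, not the
biology's cooperativeness.

## Problem sizes

The test suite runs the full pipeline on bundles of 40–70 transcripts and
the recovery analyses on 500 coding / 400 lncRNA / 50 snoRNA transcripts;
`scripts/acceptance.py` uses the same 950-transcript experiment. These
sizes give the medians and proportions stable sampling error (the CDS fold
medians move by a few percent between seeds) while the whole suite stays
fast.

## Known limitations

- The calibration needs a start-codon pileup and codon phasing to resolve
  the ±1 ambiguity; very sparse length strata (a handful of reads) can
  still miscalibrate by 1 nt, which is why strata without upstream signal
  inherit the pooled offset.
- RR scores with the default +1 pseudocount compress extreme ratios for
  very low counts; the pseudocount is a parameter.
- The spike-in is modeled (and consumed) as a single aggregated feature;
  fragment-level spike heterogeneity is not represented.
- `classify_lncrna` classifies transcripts, not ORFs; a transcript with one
  translated and several untranslated ORFs is simply "translated".
- Open-ended ORFs (no in-frame stop) are enumerated but excluded from
  scoring, since every score needs a defined ORF interval.
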