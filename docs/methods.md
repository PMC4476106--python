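# Methods

## The analysis model

The pipeline treats a miRNA–gene pair as a candidate repressive interaction
when three independent lines of evidence agree: both features are
deregulated between quiescent and activated HSCs, their expression is
significantly negatively correlated across the HSC samples, and a
sequence-based database predicts the interaction. Each stage is a pure
function over pandas DataFrames; the `run_pipeline` orchestrator executes
normalize → detect → classify → integrate → summarize and logs
`key=value` feature counts per stage.

### Normalization and group statistics

miRNA abundance enters as raw Ct (threshold-cycle) values. One PCR cycle is
one doubling, so after normalization to the reference assay (RNU6),
−ΔCt = −(Ct_assay − Ct_reference) is a log2-scale abundance. The transform
is exact and parameter-free; it is invariant to any per-sample additive
shift of Ct, which is what makes the reference normalization meaningful.
Undetermined wells are either assigned the maximal cycle (40, default) or
kept missing; both policies are exposed because array exports differ and the
correct choice is a property of the instrument software, not of the
analysis.

Fold changes are computed from *group means on the log2 scale* and then
exponentiated — not as the mean of per-sample ratios — and reported both as
a linear ratio and in the signed convention (ratios < 1 become −1/ratio, so
a relative expression of 0.68 prints as −1.47). Significance is the
classic equal-variance two-sided Student t-test. Degenerate inputs follow
fixed conventions: zero pooled variance gives p = 1 for equal means and
p = 0 otherwise; groups with fewer than two observed values give a missing
p-value while the fold change is still reported. A paired test (donors
contribute one quiescent and one activated sample each) is available but
off by default: the group-mean fold-change definition is an unpaired
statistic, and the default keeps the two consistent.

Detection: an assay is "expressed" when its Ct is ≤ 35 in at least half of
the samples (rounded up) of at least one state group, with undetermined
wells at Ct 40. These are conventional TaqMan-array thresholds, and both are
configuration fields.

### Differential classification

Genes: `q_associated` requires ≥ 2-fold enrichment over hepatocytes AND over
LSECs in qHSCs, plus ≥ 1.5-fold down-regulation on activation;
`a_associated` requires the same double 2-fold enrichment in aHSCs plus a
significant (p ≤ 0.05) up-regulation from quiescent to activated. The
cell-type enrichment filters are fold-change-only; the significance
requirement applies only to the quiescent/activated contrast. miRNAs:
`q_associated` at ≥ 1.5-fold down on activation, `a_associated` at ≥ 2-fold
up, both with p ≤ 0.05. Ties at a threshold pass ("at least two-fold").
The two direction conditions are mutually exclusive, so labels are unique;
all thresholds are configuration fields with these defaults.

### Integration

All deregulated miRNA × deregulated mRNA pairs are Pearson-correlated over
the HSC samples shared by both matrices (hepatocyte/LSEC samples carry no
miRNA data and are excluded). The two-sided p-value uses the exact
t-distribution with n−2 degrees of freedom; |r| = 1 maps to p = 0. Fewer
than 3 shared samples is an error. Zero-variance or incomplete feature
vectors get a missing r and are excluded from the FDR family.

Benjamini–Hochberg adjustment is applied to all pair p-values as a single
family (the procedure describes one final FDR cut, not a per-miRNA one);
the implementation delegates to statsmodels' step-up routine and is checked
in the tests against a literal brute-force transcription of the step-up
definition. Selection uses a two-sided correlation test plus an explicit
r < 0 filter (mirroring the stated pair of conditions), strict inequality
for FDR < 0.05 and p_database < 0.05, and non-strict p ≤ 0.05 for the
t-tests — matching how each criterion is conventionally printed. Pairs
absent from the prediction table are retained with missing p_database and
`selected = False` so database coverage remains auditable.

### Summaries

Targets per miRNA counts *selected* pairs, reporting explicit zeros. The
quiescence panel keeps q-associated miRNAs with strictly more than
`panel_min = 6` functional targets ("more than 6"; the bundled panel's
minimum is 7, consistent with the strict reading — strictness is
configurable). Class statistics use the n−1 sample SD. Because a class mean
over *all* members is diluted by miRNAs with zero selected targets, the
mean/SD restricted to members with ≥ 1 target are reported alongside;
neither denominator is privileged. Coverage is |union of the panel's
selected target genes| / |a-associated genes|. Percentages round
half-away-from-zero to integers. The most-targeted gene maximizes the
number of distinct selected miRNAs targeting it; ties are all reported,
alphabetically.

## The synthetic-data generator

The generator emulates the study design: `n_donors = 4` donor pairs
(quiescent + activated HSC samples), 2 hepatocytes, 3 LSECs; 20
quiescence-enriched miRNAs with Poisson-mean 15 activation-induced targets
each versus 50 activation miRNAs with mean 1.5 quiescence-specific targets;
gene pools of 60 qHSC-specific, 150 activation-induced and 100 background
genes (a scaled-down version of a ~1000-gene up-regulated set).

On the log2 scale each feature is baseline + planted state effect
(`effect_log2 = 3`, i.e. 8-fold) + per-sample biological deviation
(`donor_sd = 0.5`) + measurement noise (`noise_sd = 0.25`). Additive
Gaussian noise on the log2/−ΔCt scale is the simplest model consistent with
analyzing log-scale data; the within-group biological deviation is a free
knob (real within-group correlation for these cells is not characterized)
and exists because the correlation stage needs structure beyond group
means. Repression is encoded by propagating each regulator miRNA's
biological deviation into its target with negative unit coupling (averaged
over regulators), so true pairs are anticorrelated *within* groups as well
as through the state contrast; in the noiseless limit a singly-regulated
pair is exactly r = −1. miRNAs are delivered as Ct against a simulated
reference assay with a state-independent mean and small (0.1 cycle) noise,
exercising the normalization stage; the reference noise cancels exactly in
−ΔCt. Quiescence-specific genes are elevated only in qHSC samples;
hepatocyte/LSEC samples sit at baseline for every gene, and the repression
coupling applies only in HSC samples, where miRNA data exist.

The prediction table lists every true pair — significantly
(p_database ∈ [0.001, 0.04]) with probability `db_sensitivity = 0.9`,
otherwise non-significantly (p ∈ [0.06, 0.9]) — and each non-pair
significantly with probability `db_fpr = 0.01` plus non-significantly at a
background rate of 0.1. The sub-ranges straddle the 0.05 cut with a gap so
no emitted value is ambiguous at the threshold. One top-level seed drives
deterministic per-stage child streams (truth, expression, database), so a
config + seed reproduces the dataset byte for byte.

What the generator does **not** emulate: sequence content and 3'UTR
alignment (the prediction table is sampled, not computed), pre-amplification
bias, amplification-efficiency differences, heteroscedastic or outlier
noise, and realistic correlation among non-interacting features. Passing
recovery tests therefore demonstrates that the pipeline's logic implements
its stated filters correctly under the design's signal-to-noise regime, not
that the filters have any particular operating characteristic on real
arrays.

An important consequence of the strong planted state effects: with 8-fold
contrasts and only 8 HSC samples, *every* opposite-direction deregulated
pair is strongly anticorrelated through the group contrast alone, so the
prediction-table filter carries most of the specificity (precision ≈
1 − expected false predictions / selections). This mirrors the real
analysis, where correlation across a quiescent/activated contrast cannot by
itself distinguish direct targets from co-regulated genes. For the same
reason the null-calibration check uses a full null (no planted network *and*
no state effects): with effects but no coupling there is no meaningful
"null" correlation structure to calibrate against.

## Problem sizes and numerical choices

The recovery evaluation averages precision/recall over 10 simulation seeds
of the default design (~70 miRNAs × ~310 genes, ≈15,000 tested pairs per
run); the null calibration uses 10–20 seeds. These sizes give stable
seed-averaged statistics while keeping a full test-plus-acceptance run in
well under a minute of compute. Matrix round-trip equality is asserted to
1e−9 (files store 10 significant digits). BH adjustment, Pearson p-values
and t-tests are exact library routines; the only hand-set conventions are
the zero-variance t-test values and p = 0 at |r| = 1.

## Known limitations

- The unpaired default t-test ignores the donor pairing; the paired option
  exists but changes the group-mean fold-change interpretation.
- Correlation over 8 samples has low power; the FDR family is large, so
  recall depends mainly on the planted effect size.
- The panel-table parser accepts only the two printed dialects
  (decimal-comma and centered-dot scientific notation); it is not a general
  locale-aware number parser.
- Class target statistics over all members versus over members with ≥ 1
  target can differ substantially when many class members have no selected
  target; both are reported and the choice is left to the reader.
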