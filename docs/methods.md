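# Methods

## Amplicon geometry

An amplicon model is purely geometric: a length plus ordered cut sites,
each with an enzyme and the methylation state under which it cuts.
Coordinates are 0-based cut offsets from the 5′ end, so a single cut at
position *p* yields fragments of length *p* and *L − p* and fragment
lengths can be read directly off coordinates. Pattern strings name the
5′-most site first.

The built-in models are fixed by the published band lists rather than by
primer sequences (the Alu primer contains degenerate bases, so a purely
sequence-level definition is not unique):

* **LINE1_92** — 92 bp; TasI-when-unmethylated at 32, TaqI-when-methylated
  at 50. This is the only assignment that reproduces all four
  representative bands (mCmC→50, uCmC→18, mCuC→92, uCuC→60), in
  particular the 18 bp middle fragment of the double digest.
* **ALU_133** — 133 bp; TaqI-when-methylated at 43 and 75, fixed by the
  single-cut pairs {43, 90} and {75, 58}. The double digest reads
  43, 32, 58 from the 5′ end — the only ordering consistent with
  mCuC→90 and uCmC→75.

Neither amplicon's physical 5′→3′ orientation is stated anywhere; the
orientation used is the unique one consistent with the printed
band-to-pattern mapping. Sequence-level operations (in-silico bisulfite
conversion, motif scanning) exist for assay-design work but the analysis
path never needs a sequence.

## Effective lengths

Two divisor tables convert band intensity to molar quantity:

* `geometric` — fragment length minus the summed 5′ overhangs of its
  enzyme-cut ends (TaqI 2 nt, TasI 4 nt, blunt 0). Derived entirely from
  the model's end labels.
* `as_printed` (default) — the fixed divisors of the original analysis.
  These agree with `geometric` everywhere except two Alu entries: the
  uncut 133 bp product is divided by 131 (not 133) and the doubly-cut
  32 bp fragment by 30 (not 28). The discrepancy is unexplained at the
  source; `as_printed` reproduces it verbatim without interpretation, and
  a fixture test documents exactly which entries differ.

The invisible 18 bp LINE-1 band has no published divisor; the geometric
value (18 − 4 − 2 = 12) is used in both modes in the rare case it is
quantified directly.

## F inference (LINE-1)

The 18 bp band cannot be measured, so its quantity F is inferred. The
band-sharing identities D = C + F (42 bp band) and E = B + F (32 bp band)
have the unique least-surprising solution

    F = ((D + E) − (B + C)) / 2   (default, "algebraic")

The formula as originally printed has (B − C) in place of (B + C). Under
it a fully methylated lane (B = 0, D = E = C > 0) would yield a spurious
F = C > 0, which is why it is treated as a sign error; it remains
available behind `f_variant="as_printed"` for exact reproduction, and is
never chosen silently. Negative inferred F — routine under densitometry
noise — is clamped to zero and flagged `negative_F_clamped` rather than
raised, since a hard error would discard otherwise usable lanes.

## Deconvolution and QC

Frequencies use only the four representative quantities (LINE-1:
A, B, C, F; Alu: A, C, D, F — the redundant Alu bands B and E are
excluded from the denominators exactly as in the original arithmetic, to
avoid double counting). Both assays satisfy, algebraically,
%mC = %mCmC + (%uCmC + %mCuC)/2, and frequencies are invariant to lane
intensity scale; both facts are asserted as property tests. The redundant
bands feed consistency residuals (Alu: B − (C+F), E − (D+F); LINE-1:
D − (C+F), E − (B+F), each relative to the lane total), which vanish on
noise-free lanes and provide a per-lane QC signal otherwise.

## Inter-assay normalization

The original protocol normalized samples against HeLa, Jurkat and Daudi
control DNA run in every batch but gives no arithmetic. The scheme here is
additive on the frequency scale: per batch, assay and pattern, subtract
the mean deviation of the batch's control measurements from their
references (grand mean of each control line across batches), clamp at
zero, renormalize the four patterns to 100 and recompute %mC. Additive
zero-sum batch shifts are removed exactly; the step is **off by default**
because it is a documented choice, not a published procedure.

## Cohort statistics

Pairwise tests are two-tailed and independent-sample. The normality gate
is Shapiro-Wilk at α = 0.05 applied to both groups (the original analysis
names neither test nor threshold); both passing routes to a
pooled-variance Student's t, otherwise Mann-Whitney U — exact when both
n ≤ 20 without ties, else normal approximation with continuity correction
(cohort sizes of 12–29 straddle exact feasibility). The default
comparison table covers each assay × cell type × metric (overall %mC, the
four patterns, combined partial methylation uCmC + mCuC) for active vs
control, inactive vs control, active vs inactive and all-patients vs
control, with no multiple-testing correction by default (matching the
original report); Benjamini-Hochberg is available behind a flag because
the table has ~100 rows.

From the published Alu summary table, the pooled test reproduces the four
uCuC footnotes (0.03, 0.03, 0.002, 0.006) at printed precision. The
partial-methylation footnote (0.02) is reproduced by the Welch variant
(pooled gives ≈0.014); the remaining partial-methylation entry (printed
0.055) is reproduced by neither variant (pooled 0.017, Welch 0.035) and is
recorded in the fixtures without an assertion. The published LINE-1 PBMC
control row prints identical values for %mC and %mCmC (81.76 ± 2.04),
inconsistent with every other mCmC entry (~68); the row ships verbatim but
flagged `suspected_typo` and is excluded from quantitative checks.

## Synthetic studies

The generator emulates the original design: cohorts of 15 controls, 12
active and 17 inactive subjects, PBMC and neutrophil lanes, both assays,
with the published per-group pattern means/SDs as sampling targets (for
the flagged LINE-1 mCmC entry the target is completed from the simplex,
100 − Σ others = 68.74, with the median SD of the remaining patterns).

Per-sample frequency vectors are independent truncated normals (at zero)
renormalized to sum 100. Renormalization mixes variance between patterns,
so the pre-normalization SDs are inflated by solving the delta-method
fixed point var_out_j = (1−p_j)² v_j + p_j² Σ_{k≠j} v_k for the target
variances; targets below the cross-talk floor of the other patterns are
clamped at zero pre-variance, leaving the output SD at that floor (for
the Alu neutrophil-control row the uCuC SD lands near 1.35 against a
target of 1.03 — measured, and bounded, by a dedicated test). Means are
distorted by under 0.2 points throughout.

Lanes are rendered through the forward model: pattern quantity × band
divisor × scale × per-batch gain, one lognormal multiplicative noise draw
per band (default σ = 0.05 — roughly proportional error on positive
intensities), with the 18 bp LINE-1 band omitted by default so the
F-inference path is always exercised. Per-batch additive frequency
offsets can be injected to test normalization; the three control cell
lines are fixed, configurable truth vectors (none were published). What
the simulator deliberately omits: bisulfite conversion failure, PCR bias
between methylation states, gel smearing, and within-subject correlation
between cell types or assays (every measurement is drawn independently).
Passing tests therefore validate the arithmetic and the statistical
calibration of the pipeline, not the biology of any real cohort — the
published group means/SDs themselves are not recoverable from first
principles because no raw densitometry was deposited.

## Problem sizes and numerical choices

The calibration tests use 150 null studies (44 Alu neutrophil lanes each,
24 p-values per study → 3600 null p-values; observed type-I ≈ 0.043 at
α = 0.05), 30 replicate studies for the power check of the
inactive-vs-control uCuC separation, and 50 samples per group at σ = 0.05
for parameter recovery (group means within 0.5 points of simulation
truth). The round-trip identity (forward render → quantify → deconvolve)
is asserted at 1e-9 over 1000 random simplex vectors. Degenerate inputs:
all-zero lanes, zero denominators, constant samples and sub-3 groups all
raise informative errors rather than propagating NaN; two identical
constant samples compare with p = 1 and a `degenerate` flag.
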