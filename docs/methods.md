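# Methods

## The sequence-score model

The core statistic is a linear score over base-composition features of a
gapmer ASO:

    score = p_A·n_A + p_T·n_T + p_C·n_C + p_G·n_G + p_3·g_3 + I

*n*_A, *n*_T, *n*_C, *n*_G count the four nucleobases (LNA and DNA
positions count alike; no difference between sugar chemistries in their
contribution to acute neurotoxic potential has been observed, so features
are computed at the base level). *g*_3 is the number of consecutive
non-guanine bases counted inward from the 3′ terminus: 0 when the 3′ base
is G, the full length when the sequence contains no G. The model is
deliberately simple — dinucleotide/trinucleotide expansions and
tree-ensemble models do not improve accuracy for this endpoint and invite
overfitting, so they are out of scope.

Coefficients are estimated by ordinary least squares against measured
calcium-oscillation scores (percent of untreated control) via
`statsmodels.OLS` (QR-based). Inference is the standard OLS apparatus:
per-coefficient standard errors, t-statistics, and two-sided p-values on
n − 6 residual degrees of freedom. The fit requires at least 7
observations and a full-rank design; rank deficiency is reported with the
names of the collinear columns. Calcium scores enter the fit raw — the
occasional capping of scores at 200 is a display convention, exposed as an
optional `cap` argument but off by default.

Calculated scores are reported raw, with integer rounding available where
a printed-table convention is wanted.

## Tolerability scale and classification conventions

Per-mouse tolerability is the sum of five behavioral category scores
(each 0–4), giving 0–20; per-ASO scores average 4–6 mice. Severity bins
partition [0, 20] as mild [0, 4), moderate [4, 7), marked [7, 18], severe
(18, 20]. The binary endpoint is **acceptable iff score ≤ 4** (the
boundary value 4 is acceptable for the binary task even though it falls in
the moderate severity bin; the source material states both conventions and
the explicit "at or below 4" rule wins for classification).

Classifier evaluation treats *toxic* as the positive class and orients the
predictor so that higher = safer: predicted toxic iff predictor ≤ cutoff.
AUC equals the probability that a random toxic ASO scores below a random
acceptable one, ties counting ½ (verified against exhaustive
Mann–Whitney pair counting). The accuracy-vs-cutoff curve uses an integer
grid 0–200 by default; the reported optimal cutoff is the **midpoint of
the widest contiguous plateau** of maximal accuracy (ties broken toward
the lower plateau), which keeps the choice stable when several adjacent
cutoffs classify identically. NPV — the fraction of predicted-safe ASOs
that are truly safe — is the metric of practical interest for a
triage-before-dosing workflow. Kruskal–Wallis tests on scores grouped by
severity class use one value per ASO (the group mean), since that is the
unit of analysis throughout.

## FLIPR calcium-oscillation scoring

Traces are 1 Hz fluorescence series over a 100 s baseline, 200 s
post-addition read, and 300 s second read. "Signal increase" is
fluorescence above a per-trace baseline level estimated as the **median of
the baseline segment** — the simplest protocol-consistent reference (a
rolling-minimum alternative could be swapped in; the median was chosen for
robustness to spikes inside the baseline window). The control amplitude is
the mean, over untreated wells, of the mean detected spike height in the
300-s read; spike detection uses `scipy.signal.find_peaks` with an
absolute prominence floor (default 1 fluorescence unit) so that flat wells
are reported as an error rather than scored. Each 1-s read whose increase
exceeds 50% of the control amplitude scores 1; the per-well sum is
expressed as percent of the mean control sum, so untreated wells
self-score to 100 on average. The default scored window is the 300-s
second read — the same window that defines the control amplitude; scoring
the post-addition segment is available via the `segment` argument.

Peak counting (for the antagonist concentration–response assay) uses local
maxima with prominence ≥ 20% of the control amplitude and ≥ 2 s
separation — values needed for determinism rather than taken from any
source. The concentration–response model is the variable-slope
4-parameter logistic `bottom + (top − bottom)/(1 + (EC50/c)^h)`, fitted by
Levenberg–Marquardt least squares with EC50 optimised on the log scale and
a deterministic start (top/bottom at the response extremes, EC50 at the
geometric mean of the concentration range, slope 1). Constant responses
are flagged degenerate (top = bottom, EC50 NaN) instead of fitted.

## Negative-control design

Candidates are drawn uniformly over {A, C, T} (no G) at the configured
lengths, rejected unless |n_A − (n_T + n_C)| ≤ δ (default δ = 4, the
loosest value consistent with the published designs), and given LNA flank
patterns from the constraint list. The off-target screen slides the ASO's
reverse complement along every transcript and counts Hamming mismatches
per window — no gaps or bulges, since no gapped procedure is defined for
this screen; "fewer than three mismatched base pairs" is implemented as
≤ 2 mismatches. A design passes when no transcript contains a 0-mismatch
window and fewer than 0.1% of transcript *records* contain a ≤ 2-mismatch
window (the denominator is the number of transcripts; per-window
alternatives would need a different threshold). Survivors scoring above
70 under the fitted model are emitted ranked by descending score. How the
original 13 controls were picked from the passing pool is not an
algorithm ("preference was given…"); ranking by score is this package's
policy.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
at the original scale: a random target pre-mRNA (default 9,500 nt, GC
0.5); panels of 1,645 / 148 / 19 ASOs tiled as reverse complements of
windows in 313 / 44 / 7 disjoint target regions; lengths 14–20 nt; LNA
flanks totalling 3–9 nt split between the ends.

Generating coefficients default to p_A = 3, p_T = 1, p_C = 1.5,
p_G = −8, p_3 = 1 — the qualitative pattern of the fitted model
(guanine strongly harmful; adenine the most protective; cytosine ahead of
thymine) — with intercept 102. The intercept was set by a closed-form
calculation, not by simulation: under the tolerability link below, the
acceptable/toxic boundary falls at a true score of 70 + 15·ln 4 ≈ 90.8,
and an intercept of 102 centres the tiled-panel score distribution
(panel SD ≈ 18) so that roughly 60% of ASOs land in the acceptable class,
the split the screening campaign reports.

Measured calcium scores add Gaussian noise (sd 25, a calibration
convention) to the linear score, truncated at 0. Tolerability is driven by
the **noiseless** linear score — the in vivo response tracks the
underlying sequence effect, not the assay's measurement noise — through
the monotone link `20·logistic(−(score − 70)/15)`; each of 4–6 mice adds
Gaussian noise (sd 2), and per-mouse totals are rounded, clamped to
[0, 20], and decomposed uniformly into five category scores of at most 4.
This construction is what makes the package's headline qualitative result
reproducible: the model's calculated score, which averages away assay
noise across 1,645 training observations, classifies held-out
tolerability better than the single noisy calcium measurement does.

What the generator does **not** emulate: real target-region sequence
biases and shared motifs between panels, non-Gaussian or
score-dependent assay noise, inter-litter variability in mice, and any
biology of the specific target genes. Passing tests therefore demonstrate
correctness of the algorithms and the internal consistency of the
pipeline under its own assumptions, not predictive validity on new
chemistry.

Problem sizes in the test suite and acceptance script match the original
study (1,645 / 148 / 19; 200 Monte-Carlo replicates for coverage; 100
random ROC instances; exhaustive oracle checks at small string lengths),
which the whole pipeline completes in seconds.

## Numerical choices and degenerate inputs

- OLS: any stable least-squares path is acceptable; results agree with the
  normal equations to well below 1e-8 and are checked by residual
  orthogonality to every design column.
- Spearman p-values use the t-approximation on n − 2 df; constant inputs
  are an error (rho undefined) rather than NaN.
- Confusion metrics with zero denominators are NaN with a warning, never
  silently dropped.
- Edit distance is unit-cost Levenshtein (via `edlib`, verified against an
  independent dynamic-programming oracle, exhaustively at small sizes).
- Pairwise similarity analysis subsamples above 100,000 pairs with a
  seeded generator.
- All randomness flows through `numpy.random.default_rng` seeds; every
  generator is bit-reproducible and the CLI requires explicit seeds.

## Known limitations

- The published trained coefficients are not bundled; fitted values here
  come either from user-supplied panels or from synthetic data, so
  absolute calculated scores are comparable only within one fitted model.
- The off-target screen is complementarity-only (no thermodynamics, no
  RNase-H cleavage model) and gap-free.
- Only four-letter base identity is modelled; 5-methylcytosine and other
  base analogs are treated as their parent base.
- The FLIPR scorer assumes the fixed 100/200/300 s protocol shape
  (configurable durations, but segment semantics are fixed).
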