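# Methods

## The model

Two-sample summary-data MR treats each SNP $j$ as an instrument with an
observed exposure effect $\hat\gamma_j \sim N(\gamma_j, s_{xj}^2)$ from
one cohort and an outcome effect
$\hat\Gamma_j \sim N(\theta\gamma_j + \alpha_j, s_{yj}^2)$ from a
disjoint cohort, where $\theta$ is the causal effect per 1 SD of the
exposure and $\alpha_j$ is any direct (horizontally pleiotropic) effect.
Valid instruments have $\alpha_j = 0$; the estimators differ in what
they assume about the $\alpha_j$:

| estimator | identifying assumption |
|---|---|
| IVW | all $\alpha_j = 0$ |
| MR-Egger | $\alpha_j$ independent of $\gamma_j$ (InSIDE); intercept absorbs their mean |
| weighted median | valid instruments carry > 50% of the weight |
| MR-PRESSO | pleiotropy is confined to detectable outliers |

Binary outcomes are handled on the log-odds scale throughout; odds
ratios per 1 SD are the exponentiated estimates. For the sedentary-
behaviour traits that motivated the package, 1 SD corresponds to about
1.5 h/day of television watching and 1.2 h/day of leisure computer use;
`sd_units` carries such statements through the pipeline as metadata.

## Harmonisation conventions

The exposure table is the instrument list; every SNP ends retained or in
a drop log with one of four reasons (`missing_in_outcome`,
`allele_mismatch`, `palindromic_ambiguous`, `duplicate`), so accounting
is exact. Orientation is resolved in this order: exact allele match;
swapped alleles (outcome beta negated, EAF complemented); strand
complement of each (consortium files mix strands); otherwise a mismatch.
Palindromic SNPs (A/T, C/G) are kept only when both effect-allele
frequencies are present, both outside 0.5 ± 0.08, and on the same side
of 0.5 after nominal alignment — the conservative frequency-inference
default; anything else is dropped as ambiguous. A duplicated rsid in
the outcome file is resolved to the smallest-SE record (deterministic),
with the discards logged.

## Instrument selection

Greedy clumping on an explicit LD matrix: rank significant SNPs
(default p < 5×10⁻⁸) by ascending p with rsid as tie-break (making the
result invariant to row order), accept the best, discard anything with
r² ≥ threshold (default 0.005 univariable, 0.001 cross-trait) to an
accepted SNP within the window (default 5 Mb), repeat. Genomic positions
are an optional argument; without them every pair is treated as within
the window, which can only drop more SNPs (conservative). Without an LD
matrix the list is accepted as-is and flagged `preclumped_assumed` —
the common case, since published instrument lists arrive pre-clumped.
The package never computes LD from genotypes.

Instrument strength: per-SNP $F_j = (\hat\gamma_j/s_{xj})^2$ (values
above ~10 are conventionally adequate) and total variance explained
$R^2 = \sum_j 2f_j(1-f_j)\hat\gamma_j^2$ for a standardized exposure.

## Estimator details and numerical choices

* **IVW weights** use the first-order delta-method SE
  $s_{yj}/|\hat\gamma_j|$; second-order terms are ignored (standard
  practice). The random-effects variant is multiplicative with the
  dispersion floored at 1 and df = k−1; `auto` switches to it when
  Cochran's Q has p ≤ 0.05.
* **MR-Egger** orients every SNP to a non-negative exposure effect
  (flipping both betas), fits WLS with intercept and weights
  $1/s_{yj}^2$ in closed form, scales both SEs by
  $\max(1, \sqrt{RSS_w/(k-2)})$, and uses t(k−2) for the intercept test
  and the normal for the slope. A set whose oriented exposure effects
  have zero variance is rejected (intercept and slope not separable).
* **Weighted median** sorts Wald ratios and interpolates at normalized
  cumulative weight 1/2 with the midpoint convention
  $p_j = (S_{j-1}+S_j)/(2S_k)$. The SE is the SD of the estimate over
  1000 parametric-bootstrap resamples by default (betas redrawn from
  their sampling distributions), seeded; `n_boot=0` returns the point
  estimate alone.
* **MR-PRESSO** computes leave-one-out IVW residuals, an observed
  weighted RSS, and parametric simulations under no pleiotropy
  (exposure effects redrawn about their observed values, outcome
  effects about the leave-one-out predictions). Empirical p-values use
  the add-one estimator — resolution 1/(n_sim+1), never exactly zero.
  Note the coupling between k and simulation depth: with the Bonferroni
  adjustment the smallest attainable per-SNP p is k/(n_sim+1), so
  flagging at sig = 0.05 with k = 50 requires n_sim ≥ 1000 (the
  default). The distortion test compares the raw-minus-corrected
  displacement against displacements from removing equally many random
  SNPs (two-sided on magnitude); it is reported, never used for gating.
  All SNPs flagged is an error, not a silent empty result.
* **Multivariable MR** solves the weighted normal equations without
  intercept (weights $1/s_{yj}^2$); residual heterogeneity $Q_A$ with
  df k−L triggers the same multiplicative overdispersion when p ≤ 0.05.
  An exactly-zero exposure column denotes a null covariable: it gets
  coefficient 0 (infinite SE) and is excluded from the solve rather
  than making it singular; genuinely collinear non-zero columns raise
  an error naming the offenders. Conditional F for exposure x regresses
  its beta column on the other columns (weights $1/s_{xj}^2$) and
  reports $Q_x/(k-L+1)$; this df convention varies across the
  literature, so it is stated in every output.
* **Power** uses the binary-outcome normal approximation with variance
  factor $K(1-K)$ and two-sided α. The minimum detectable OR is the
  first grid point (step 0.01 from 1.00) whose power exceeds the
  target, cross-checked against the closed form
  $\exp\!\big((z_{1-\alpha/2}+z_{\mathrm{power}})/\sqrt{N R^2 K(1-K)}\big)$.
  Under this convention the breast (N=247,173; K=0.54; R²=0.02) and
  colorectal (N=98,715; K=0.53) designs give thresholds 1.09 and 1.14.
  The analogous prostate design is sometimes quoted as 1.11; this
  formula gives 1.12 at R²=0.020, and the discrepancy is not resolvable
  from an "approximately 2%" R² — documented rather than matched.

## The synthetic-data generator

`simulate_pair` emulates the summary-level structure the two-sample
design assumes: independent (post-clumping) instruments with
frequencies U(0.05, 0.5); true exposure effects drawn N(0,1) and
rescaled so the variance explained equals `h2x` **exactly**; direct
effects $\alpha_j = \mathrm{Bern}(\pi)(\mu_\alpha + \sigma_\alpha Z_j)
+ \psi\gamma_j$ (ψ ≠ 0 violates InSIDE); observed betas drawn with
independent noise at standard GWAS SEs, $1/\sqrt{2f(1-f)n}$, with the
$K(1-K)$ factor for binary outcomes. P-values come from the observed z
scores, floored at the smallest positive float. Defaults are the study
conditions of a large sedentary-behaviour analysis: J = 200 instruments
explaining 2% of exposure variance in N = 408,815, against a
colorectal-scale case-control outcome (N = 98,715, 53% cases) — chosen
because that design anchors the recovery checks; everything is
overridable per call.

What it deliberately does **not** model: LD between instruments (they
are independent by construction, as after clumping), sample overlap
between the two cohorts, liability-scale binary traits (effects are
generated directly on log-odds with the K(1−K) variance factor, for
consistency with the power module), winner's-curse selection of
instruments, and population structure. Passing tests therefore show
correctness of the estimators under the stated sampling model, not
robustness to those real-data complications.

`inject_outliers` adds spikes of a chosen size in SE units to selected
outcome records, recording provenance — the ground truth for outlier-
detection checks. `two_exposure_pair` adds a second exposure with a
chosen genetic correlation for multivariable and conditional-F
behaviour (e.g. r_g ≈ 0.8, the magnitude reported between television
watching and years of education, reproduces conditional F < 10 when
joint instrument strength is modest).

## Validation scales and what the checks show

The acceptance suite runs at sizes chosen to finish in minutes while
keeping Monte-Carlo error well below the effects being measured: 1000
random instances for oracle equivalence (IVW/Egger vs brute-force
weighted least squares at 1e-10 relative error; the median vs an
exhaustive interpolation oracle), 1000 null replicates for type-I
calibration (3-binomial-SD bands around 5%), 500 replicates for
recovery at θ = ln 1.32, and 100 spiked replicates for outlier
flagging. Two caveats those checks quantify rather than hide:

* **Weak-instrument attenuation.** With mean F ≈ 41 (J = 200, h2x =
  0.02, N = 408,815), IVW is attenuated by roughly $1/\bar F$ — about
  1-2% — so mean recovered ORs sit near 1.31 for a true 1.32. The
  recovery tolerance is 3 SEM plus the 0.005 print granularity of a
  2-decimal target.
* **Finite-sample median bias.** Under 30% one-sided contamination the
  weighted median is far less biased than IVW but not unbiased: with
  per-SNP Wald-ratio noise of SD ≈ 0.6 (the realistic case-control
  regime) its weighted-quantile shift is of order 0.2 log-odds,
  δ-independent once the offsets separate, while IVW's bias grows with
  the offset. The robustness check therefore asserts the median's bias
  stays within the sampling spread of a single study (3 per-replicate
  SDs) and under half of IVW's — the property that holds at any noise
  level — rather than literal unbiasedness.

## Known limitations

No proxy-SNP lookup, liftover, Steiger directionality filtering,
MVMR-Egger, or mode-based estimators. Bidirectional MR is only as good
as its instrument lists: a strong forward effect can push exposure
instruments past genome-wide significance in the outcome trait and
contaminate the reverse direction (visible in the test suite's
construction). MR-PRESSO agreement with the originally published
implementation is statistical, not bitwise. Sex-specific outcomes
analysed with sex-combined instruments inherit whatever effect
heterogeneity exists between sexes; the pipeline records this in its
run log rather than attempting a correction.
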