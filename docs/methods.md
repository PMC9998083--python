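# Methods

## Standardization and input schemas

Every association is reduced to (Z, N): the standardized effect is
β = Z/√N with sampling variance 1/N (not Z/√(N+Z²); the simpler form is
used deliberately and is accurate for the |Z| ≪ √N regime of molecular
QTLs).  Input files are tab-separated with a mandatory header; eQTL files
carry `gene_id`, mQTL files `metabolite_id`, GWAS files one phenotype per
file (named by the file stem or on the command line).  Missing p-values
(`.`) are derived from Z under the two-sided normal; a stored p-value, when
present, wins for significance thresholding so that the source study's
significance calls are reproduced.  Only biallelic A/C/G/T SNVs are
accepted; rows failing record invariants are dropped and counted in a
rejection report, while schema violations (missing columns, duplicate
(feature, SNP) pairs, empty files) are fatal.  Coordinates are 1-based,
GRCh37 by default, carried as table metadata.

Harmonization aligns outcome to exposure alleles: swapped alleles flip the
outcome sign, strand complements are tried before dropping, A/T and C/G
(strand-ambiguous) SNPs are dropped by default, and non-autosomal SNPs are
excluded.

## Instrument selection

Instruments per exposure are autosomal, non-ambiguous SNPs with
p < 1.8×10⁻⁵ (cis-eQTL) or p < 1.0×10⁻⁷ (mQTL), greedily pruned to
pairwise r² < 0.01.  The pruner visits candidates in ascending p-value
order (ties broken lexicographically by SNP id, for determinism) and keeps
a candidate iff its r² with every kept SNP is below threshold — the
index-SNP-first priority of standard clumping, without a distance window
(cis windows are assumed applied upstream).  Exposures with fewer than 3
surviving instruments are rejected and logged, not fatal.  After pruning
the LD matrix is approximated by the identity; the MR core nevertheless
accepts an arbitrary positive-definite C.  Instruments whose standardized
outcome effect exceeds their exposure effect (|γ| > |β|) are removed before
estimation as likely reverse-causal or confounded; exposures pushed below
3 instruments by this screen are rejected.

## Univariable IVW MR

α̂ = (βᵀC⁻¹β)⁻¹(βᵀC⁻¹γ), computed by Cholesky solve (a non-PD C raises an
error with its condition number; there is no silent pseudo-inverse).  The
variance is the delta-method sandwich over per-SNP sampling variances
(var(β_i) = 1/N_exposure,i, var(γ_i) = 1/N_outcome,i, zero cross-covariance
for non-overlapping samples):

    J_γ = (βᵀC⁻¹β)⁻¹ βᵀC⁻¹,
    J_β = (C⁻¹γ − 2α̂ C⁻¹β) / (βᵀC⁻¹β),
    var(α̂) = Σ J_β,i² var(β_i) + Σ J_γ,i² var(γ_i).

This is the coherent vector generalization of the scalar delta formula and
reduces to it for one instrument.  Monte-Carlo perturbation at the
reference configuration (6 IVs scaled to h² = 0.06, var_γ = 1/300,000,
var_β = 1/32,000) reproduces the delta SE to well within a percent.

### Heterogeneity (outlier) filtering

Per instrument, d_i = γ_i − α̂β_i with

    var(d_i) = var(γ_i) + β_i²·var(α̂) + var(γ_i)·α̂² + var(β_i)·var(α̂),

and T_i = d_i²/var(d_i) ~ χ²₁.  The removal loop is gated on Cochran's
global heterogeneity statistic Q = ΣT_i ~ χ²(n−1): while Q is significant
at 0.05 the instrument with the largest |d_i| is removed (ties broken
toward the weaker instrument, then lexicographically) and the fit
repeated; removal stops before the set would fall below 3 instruments, in
which case the outlier is flagged but retained.  Gating on the global Q
rather than the minimum per-SNP p keeps false removals from correctly
specified 6-IV sets at ~2–3% instead of ~14% (a union of six χ²₁ tests),
while a 10×-noise outlier is still removed first in >99% of cases.  The
var(d_i) formula ignores the negative correlation between d_i and α̂β_i
(a leverage term of order β_i²/Σβ²), which makes the per-SNP test slightly
conservative; the discrepancy is confined to the filtering loop — the
reported var(α̂) always uses the sandwich above.

## Multivariable MR mediation

For a triplet, the joint instrument list is the union of the transcript's
and the metabolite's sets; cross-set pairs with r² ≥ 0.01 keep the
transcript member (the transcript is the exposure whose direct effect is
the estimand).  Effects for every retained SNP are looked up in the full
per-feature tables — metabolite and GWAS effects harmonized to the
transcript's allele orientation — and SNPs missing from any layer are
dropped with a warning.  The direct effect is the first element of
α̂ = (BᵀC⁻¹B)⁻¹(BᵀC⁻¹γ) with B the n×2 matrix of (transcript, metabolite)
effects.  Fits with cond(BᵀC⁻¹B) > 10¹² (condition number of the whitened
design above 10⁶) are rejected as collinear.  Its variance is the
delta-method analogue: the outcome-noise term
S⁻¹BᵀC⁻¹ diag(var γ) C⁻¹B S⁻¹ plus exposure-noise terms from the gradient
of α̂ with respect to each entry of B.  No heterogeneity loop runs inside
MVMR; instruments arrive pre-filtered from the univariable stages.

The indirect effect is defined by subtraction, α_i = α_TP − α̂_d, so
total = direct + indirect holds exactly for every triplet.  Its reported
SE is √(SE_total² + SE_direct²), which ignores the (positive, not
separately identifiable) covariance between the TWMR total and the MVMR
direct estimate and is therefore conservative.

The across-triplet proportion of direct effect is the through-origin
regression slope of α̂_d on α̂_TP (an intercept can be enabled by flag, but
both effects are expected to vanish together, so through-origin is the
default), divided by 1 − ΣSE(α_TP)²/Σα_TP² to undo errors-in-variables
attenuation; a noise-to-signal ratio ≥ 1 is an error state.  The 95% CI is
a seeded percentile bootstrap over triplets (2,000 replicates).

## Multiple testing and triplet assembly

Benjamini–Hochberg q-values are computed per scan over the family of all
instrumentable exposure × outcome pairs; pairs that fail after
harmonization still count in the denominator (implicit p = 1), which the
hand-rolled step-up supports via an explicit family size.  Triplets join
TM and MP hits at FDR ≤ 5% on the shared metabolite; the composite level
1 − 0.95² = 9.75% assumes independence of the two screens and is reported
as such, without an independence diagnostic.  TP significance is not
required for triplet membership; when the TP link does pass, a concordance
flag records whether sign(α_TM·α_MP) = sign(α_TP).

## Synthetic data

The generator emulates the statistical structure of public multi-omics
summary data, directly on the standardized scale (no individual-level
phenotype simulation): per-feature instrument effects are scaled so
Σβ² = h² exactly (defaults h²_T = 0.06 over 6 SNPs, h²_M = 0.04 over 5);
marginal effects propagate through the planted chain (metabolite = own
instruments + Σ α_TM·transcript effects; phenotype = direct + mediated);
each layer observes truth + Normal(0, 1/N) per SNP, with default
N_eQTL = 31,684, N_mQTL = 8,000, N_GWAS = 300,000.  Planted instrument
effects use near-equal magnitudes with random signs rather than Normal
draws: real QTL instruments are by construction significant, whereas
Normal-drawn effects at these h² and N would frequently fall below the
selection thresholds and de-instrument their features.

The reference panel draws block-structured dosages: each SNP copies each
of its two allele draws from the block's index SNP with probability √r,
which preserves the marginal MAF exactly and yields within-block dosage
correlation ≈ r (√r against the index SNP).  Blocks are independent;
positions are spaced 10 kb and blocks cycle the 22 autosomes.  Effect
noise is independent across SNPs, so LD enters fixtures only through the
pruning step.

What passing tests on these fixtures do *not* show about real data: no
winner's curse (instruments are planted, not discovered), no sample
overlap between layers, no allele-frequency or metabolite-correlation
realism, no population stratification, and LD that is block-diagonal by
construction.

Presets: `triplet` (one planted chain α_TM = 0.3, α_MP = 0.2, direct = 0
among null features), `null` (100 instrumented transcripts, 10
metabolites, no cross-layer effects), `fads-like-hub` (one transcript
feeding three metabolites that hit one phenotype), `dilution` (500
triplet-level effect estimates with true direct proportion 0.8 and known
total-effect SEs — generated at the effect level because the dilution
correction consumes only effect estimates).

## Power simulation

Scenarios fix the total effect α_TP = 0.035 and vary ρ (proportion
direct) over [−2, 2] (51 points; ρ outside [0, 1] covers opposing direct
and indirect effects) and σ = α_TM/α_MP over [0.1, 10] (51 points,
geometric — σ is a ratio, so spacing is log-symmetric around 1).  Two
parameterizations are implemented because the printed recipes
α_TM = α_TP(1−ρ)σ and α_MP = α_TP(1−ρ)/σ imply product α_TP²(1−ρ)² and
ratio σ², which contradicts the stated identities α_TM·α_MP = α_TP(1−ρ)
and σ = α_TM/α_MP.  The default `literal` mode follows the recipes
verbatim; `consistent` mode solves the two identities exactly (the sign
going to α_MP when α_TP(1−ρ) < 0).  The choice is recorded in the run
manifest.

Per repetition, true instrument effects are drawn Normal(0, h²/n_IVs);
the observed outcome adds Normal(0, 1/N_outcome) noise and the observed
exposure optionally adds Normal(0, 1/N_exposure) (default on — the eQTL
and mQTL sample sizes enter only through this term).  Every simulated fit
runs the same IVW + delta-variance + global-Q filtering as the pipeline,
via a fast identity-LD path that is property-tested to agree with the
general implementation to 10 significant figures; a flag disables the Q
filter for speed and for comparison against the analytic oracle, which
models the no-exposure-noise, no-filter regime (Σβ² ~ (h²/n)χ²(n), Z
noncentrality |α|√(N·Σβ²)).

Power_TP and power_TM average over `n_transcripts` repetitions (default
500), power_MP over transcript×metabolite pairs capped at a configurable
budget (default 4,000 of the 500×80 design, chosen to keep a full 51×51
grid at desk scale); each (cell, repeat) derives its seed from
(master seed, ρ index, σ index, repeat), so grids are bit-reproducible
and parallelizable.  Grid exports are TSV matrices with σ descending in
rows and ρ ascending in columns.

One known discrepancy is surfaced rather than hidden: at the reference
conditions the analytic oracle and the simulator both put the power of
the direct TP test near 0.94, not the ~65% sometimes quoted for
α_TP = 0.035 at nominal 5%; the generating process behind that figure
appears under-specified (e.g., the placement of estimation noise or an
unstated threshold), so it is treated as a soft diagnostic, not a target.

## Numerical and design choices

- All linear algebra through Cholesky solves; decomposition failures raise
  with a condition-number report.
- Determinism throughout: every stochastic component takes a seed or a
  `numpy` SeedSequence; pipelines with identical inputs produce
  byte-identical TSVs.
- Tie-breaks (pruning order, outlier choice) are lexicographic after the
  primary criterion, so results do not depend on input row order.
- Degenerate inputs are explicit error states: all-zero exposure effects,
  non-PD LD, collinear MVMR designs, dilution noise-to-signal ≥ 1,
  |α_TP| < 10⁻¹² in proportion computations (flagged undefined).
- Test and acceptance problem sizes (e.g. 10,000 reps for calibration
  bands, 20 synthetic studies for recovery checks, 5×5 grids at 200
  transcripts × 2 repeats) are the package's chosen desk-scale defaults;
  they keep Monte-Carlo error well inside the asserted tolerances.

## Limitations

- Univariable estimators only (no Egger/median/mode alternatives); one
  metabolite per MVMR (no multi-mediator models); no reverse-causality
  testing of metabolite → transcript directions.
- The composite 9.75% FDR assumes screen independence.
- Mediation estimates are lower bounds when mediators are unmeasured or
  uninstrumented; correlated mediators can masquerade for one another.
- Only biallelic SNVs; no liftover, no VCF input, no cis-window
  computation (assumed applied upstream).
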