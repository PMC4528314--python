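# Methods

This note documents the models implemented in `crossblup`, the assumptions
behind the synthetic-data generator, the numerical choices, and what the
package's tests do and do not demonstrate about real data.

## Models

### Deregression

An EBV is a shrunken predictor of an animal's additive genetic merit that
mixes parent-average (PA) information with the animal's own information
(own and progeny records). Used directly as a response in genomic
prediction, EBVs double-count family information. Deregression undoes this.

`simple` mode divides by the reliability, DEBV = EBV/r². `parent_adjusted`
mode solves, per animal, for the pair of information contents
(Z′Z_PA, Z′Z_i) that reproduce the observed reliabilities under the
two-effect mixed-model equations

    [ Z′Z_PA + 4λ   −2λ    ] [ĝ_PA]   [y*_PA]
    [ −2λ       Z′Z_i + 2λ ] [ĝ_i ] = [y*_i ],   λ = (1−h²)/h²,

where the λ-terms are σ²_a × the inverse of the PA/individual relationship
matrix [[½, ½], [½, 1]]. With C the inverse coefficient matrix, the
individual's reliability is r²_i = 1 − λC₂₂ and the parent-average
reliability (in the predictor-of-the-individual convention,
r²_PA = (r²_sire + r²_dam)/4 < ½) satisfies 1 − 2r²_PA = 2λC₁₁/… — the two
equations reduce to a quadratic with a closed-form root (see
`deregress._solve_information`). The DEBV is the solved own-information
pseudo-record y*_i / Z′Z_i with reliability Z′Z_i/(Z′Z_i + λ). Feeding the
solved system back through the equations reproduces the input EBV and r²
to 1e−8; this round trip is the module's defining contract and is enforced
on 1,000 records in the test suite. Reliability pairs that are infeasible
under the two-effect model (non-positive information) fall back to simple
mode with a logged count, as do animals without usable parent records.

Residual weights follow w = (1−h²)/((c + (1−r²)/r²)h²) with c (the
fraction of genetic variance not captured by markers) defaulting to 0 and a
reliability cap at 0.99 to avoid infinite weights; the record's residual
variance in later models is σ²_e/w.

### Relationship matrices

**A** is built by the tabular method over the topologically sorted
pedigree: a_ii = 1 + ½a_{sire,dam}, a_ij = ½(a_{j,sire(i)} + a_{j,dam(i)}),
unknown parents contributing zero. Tests check it exactly against an
independent recursive-coancestry oracle on small pedigrees.

**G** (within-population) is VanRaden's first form, G = ZZ′/(2Σpᵢqᵢ), with
Z column-centered at the observed (or supplied) frequencies. Under
observed-frequency centering every row of G sums to zero, and G is
invariant to per-SNP allele-coding flips — both are tested identities.

**G** (across-population) centers each animal's genotypes with its own
line's allele frequencies, so mean allele-frequency differences between
lines do not register as relatedness. The default `blockwise` denominator
divides the (line j, line k) block by √(dⱼdₖ), dₗ = 2Σp_l q_l, which makes
each within-line block exactly the line's own VanRaden matrix — the
property the within/multi/across comparisons rely on. A single pooled
denominator is available for sensitivity runs. F1 frequencies default to
the observed F1 frequencies when ≥ 30 F1 are present, else the mean of the
parental lines' frequencies (`f1_line_freqs`).

Before inversion, any K whose smallest eigenvalue is below 1e−8 receives a
ridge ε = 1e−6 × mean(diag); the perturbation is recorded in the solver
metadata. G from finite SNP panels is routinely singular, so this is the
expected path, not an exception.

### Mixed models and REML

`solve_blup` assembles Henderson's MME in the R⁻¹ parametrization (so the
inverse coefficient matrix directly yields prediction-error variances),
with R = diag(σ²_e/wᵢ) and var(g) = Kσ²_a over *all* animals in K; animals
without records are predicted through relationships alone. Reliability is
1 − PEV/(K_ii σ²_a) (the K_ii factor matters for inbred animals).
Problem sizes here are a few thousand animals, so dense Cholesky/LU
factorizations are used throughout; no sparse inverse machinery.

`reml_univariate` offers two algorithms. `em` is classic EM-REML on the
MME — σ²_a ← (û′K⁻¹û + tr(K⁻¹C_uu))/q, σ²_e ← y′W ê/(n−p) — whose
restricted likelihood is non-decreasing (a tested invariant) but which
crawls near boundaries. `ai` (the default) performs average-information
updates on the marginal covariance V = σ²_aK + σ²_eD with step halving
against the restricted likelihood and converges in a handful of
iterations; standard errors come from the inverse AI matrix. Convergence:
relative parameter change < 1e−8 or |Δloglik| < 1e−10; non-convergence
within `max_iter` returns the last iterate flagged `converged=False`.

`reml_bivariate` treats the purebred- and crossbred-expressed trait as two
traits with additive covariance **G₀** ⊗ **A**. Because each animal carries
at most one of the two records, the residual covariance is not estimable
and is fixed at zero. The variance is linear in
θ = (G₀₁₁, G₀₁₂, G₀₂₂, σ²_e1, σ²_e2), so the same AI machinery applies;
G₀ is kept positive semidefinite by bending |G₀₁₂| to 0.999·√(G₀₁₁G₀₂₂)
when an update leaves the cone (bends are counted in the result). Starting
values come from per-trait univariate fits (or can be supplied). The
genetic correlation is r_g = G₀₁₂/√(G₀₁₁G₀₂₂) with a delta-method standard
error. Fixing G₀₁₂ = 0 reproduces the per-trait univariate fits, a tested
reduction.

### Scenarios

Seventeen designs in four groups mirror the standard
within/multi/across/PB→CB comparison grid: within-population (validation =
50 held-out animals of the training line, 20 replicates), multi-population
(other line(s) added to training), across-population (one line predicts
the whole other line; single replicate when all animals train), and
purebred→crossbred (PB lines train, all F1 validate). "Reduced" variants
equalize per-line training sizes at one common N — by default the smallest
population's usable training count — so composition effects are not
confounded with size. Replicate sampling streams depend only on (scenario
id, base seed, replicate index); GBLUP and PED-BLUP therefore see identical
splits and are compared paired. PED-BLUP is skipped for the
across-population group: two purebred lines share no pedigree, so **A**
carries no information between them. Accuracy is the Pearson correlation
between predictions and validation DEBVs; bias is the OLS slope of DEBV on
GEBV, and because both regression conventions circulate, the reverse slope
is always emitted alongside. Zero-variance predictions yield an undefined
accuracy (NaN) that is excluded from means and counted, never imputed as 0.
Variance components are re-estimated by REML on each training set by
default; a fixed-components mode exists for speed and for sensitivity
analysis.

## The simulator

`simpop` generates the data structure this analysis assumes, with defaults
chosen to resemble a two-line pig nucleus at desk scale: 2 purebred lines ×
1,200 genotyped sows + 290 F1, 5,000 SNPs of which 500 are QTL, founder MAF
uniform on [0.1, 0.5], 30 generations of drift at Ne = 100 (expected
Fst ≈ 0.14), h² = 0.3, r_g(PB,CB) = 0.6, line means 0 / 0.5 / 0.25, 1 %
missing genotypes, 4 parities per sow.

Mechanics and their justifications:

- **Drift**: line allele frequencies evolve by binomial resampling of 2Ne
  gametes per generation. Realized Fst is measured against the known
  founder frequencies, mean(p_l − p₀)²/mean(p₀q₀), whose expectation is
  exactly 1 − (1 − 1/2Ne)^t; the test suite verifies this against the
  Wright–Fisher closed form by Monte Carlo.
- **Family structure**: per line, 200 unrelated base animals (drawn
  Hardy–Weinberg at the drifted frequencies) are mated at random (25 %
  sires) for two generations; the genotyped cohort is generations 1–2, so
  **A** contains parent–offspring and sib structure and PED-BLUP has real
  information. SNPs assort independently — there is no linkage map and
  therefore no LD beyond what family structure and drift create. This is a
  deliberate reduction: the estimators under test (deregression, A/G
  construction, REML, the scenario engine) do not use map positions, but it
  means across-population accuracy here reflects family links and directly
  genotyped QTL rather than LD consistency, and absolute accuracies should
  not be read as forecasts for chip data.
- **Separation of purebreds and crossbreds**: two multiplication-tier
  generations (unGenotyped, but carrying records, as commercial sows do)
  stand between the nucleus cohorts and the F1 parents (76 sires × 170
  dams). Without this tier, an F1 validation animal's own record flows into
  its genotyped ancestors' EBVs ("own information" under deregression
  includes progeny records) and returns through the relationship matrix as
  spurious prediction accuracy — a circularity the real populations, where
  generations and farms separate the genotyped sets, did not have. With the
  tier in place, purebred→crossbred accuracy at r_g = 0 is statistically
  zero (0.015 ± 0.021 across 12 seeds in the development runs) while
  r_g = 0.9 gives ≈ 0.36.
- **Traits**: QTL effect pairs (u_pb, u_cb) are bivariate normal with
  correlation ρ; purebreds express u_pb, F1 express u_cb — the standard
  reduction of the two-trait PB/CB model, additive only. TBVs are rescaled
  so the within-line additive variance equals h² of a unit single-record
  variance. Each sow's phenotype is the mean of 4 parity records
  (residual variance (1−h²)/4), matching the records-per-animal ratio of
  multi-parity sow data; records enter PED-BLUP with weight 4.
- **Pseudo-EBVs**: the package's own PED-BLUP (line fixed effect, true
  variance components) runs on all phenotypes, and EBVs/reliabilities
  (r² = 1 − PEV/(A_ii σ²_a), clipped to [0.01, 0.99]) are published for
  every pedigree animal, mirroring a routine evaluation — unphenotyped
  connectors receive relative-derived EBVs, which parent-adjusted
  deregression of their offspring needs. The estimated line effects are
  returned so they can be added back before multi-population prediction.

What passing tests do **not** show: realistic LD decay, genotyping error,
selection during drift, dominance or breed-specific-allele effects, and
chip-scale SNP density are all outside the generator. Conclusions about
orderings (within > across, GBLUP ≥ PED-BLUP, accuracy growing with
training size, PB→CB accuracy tracking r_g) transfer; absolute accuracy
levels do not.

## Numerical choices and degenerate inputs

- Ties in `mean_relatedness_split` break by stable animal-ID order.
- Fixed-effect line indicators use reference coding (first level absorbed
  into the intercept); accuracy and slope are invariant to the choice.
  Validation animals from lines unseen in training get a zero fixed-effect
  contribution (a constant shift, irrelevant to correlation and slope).
- Monomorphic SNP sets (2Σpq = 0), all-missing genotype columns, empty QC
  survivors, pedigree cycles, duplicate IDs, reliabilities outside (0,1],
  and training/validation overlap all raise typed `DataError`s rather than
  propagating NaNs.
- HWE χ² is the 1-df goodness-of-fit statistic over the three genotype
  classes, pooled across lines; the extreme 600 threshold makes Wahlund
  inflation immaterial, and per-line statistics are recorded in the QC
  report for diagnostics.
- Filter order: SNP filters, then the individual filter, then imputation —
  logged, single pass, no call-rate recheck.

## Problem sizes

The shipped test-suite and acceptance-script runs use reduced but
structure-preserving sizes chosen as the package's own desk-scale defaults:
parameter-recovery REML at n = 500 (univariate, 2,000 SNPs) and 1,000
records/line + 300 F1 (bivariate); scenario-ordering checks at 350–1,200
animals/line, 2,500–5,000 SNPs, 10 seeds; the determinism chain at 250
animals/line. Every such size is stated where it is used.
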