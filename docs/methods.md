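# Methods

`resilind` implements an across-breed analysis of resilience indicator
traits derived from daily milk yields of dairy cows: longitudinal
phenotyping, genomic evaluation, population-structure description, and
mixed-linear-model GWAS with evidence pooling over breeds. This note
documents the models, the parameter choices that matter, and the limits of
what the synthetic-data experiments demonstrate.

## Resilience indicator traits

For cow *i*, lactation *l*, with observed daily yields `y_t` and a fitted
lactation curve `ŷ_t` over the retained days `t` of the window (days in
milk 10–305, calving day = 0):

* **v_d** — variance of the deviations, `v_d = 1/(n−1) Σ ((y_t − ŷ_t) −
  mean(y − ŷ))²` (kg²). Small for cows with smooth lactation curves.
* **v_r** — variance of relative daily yields `α·y_t`, with
  `α = 100 / Σ y_t` so the relative yields sum to 100. Removes the
  production-level dependence; also sensitive to the rate of decline of
  the curve itself.
* **r_auto** — lag-1 autocorrelation of the deviations, numerator divisor
  `n_pairs − 1` over consecutive-day pairs, denominator divisor `n − 1`
  over all retained days. Near 0 for cows that recover quickly.

`v_d` and `v_r` are log-transformed for genetic analysis (they are
right-skewed); on the selection-index path the log values are negated so
that larger means more resilient. Records with zero deviation variance
are flagged and excluded with an audit entry. Only consecutive calendar
days form autocorrelation pairs: pairing across removed days would mix
lags and fabricate decorrelation.

One printed form of the autocorrelation numerator carries the unlagged
curve prediction on the lagged term; we treat that as a typographical slip
and use the standard lag-1 deviation product.

The selection index combines the standardized genomic breeding values of
the negated log indicators with fixed weights,
`SI = 0.65·g(−ln v_d) + 0.35·g(−ln v_r)` — weights previously derived by
maximizing correlated selection response in health traits.

## Preprocessing

Milking events are aggregated to daily yields; each day's **first milking
is split between the current and the previous day** proportionally to the
fraction of its inter-milking interval on each calendar day (a milking at
exactly midnight goes wholly to the previous day; a milking with no
predecessor stays on its own day). Total milk mass is conserved exactly.
Days that carry no recorded milking — they only receive spill-over from
the next morning — count as days *without data* for the gap rules.

Filters are applied in this order, each audited:

1. **Farm-day filter** — for each farm, days whose milked-animal count
   deviates by ≥ 3 SD (inclusive) from the farm's mean daily count are
   removed for all its animals, together with the day before and after.
   The SD is computed over all of the farm's days in the data set; farms
   with fewer than two days are skipped with a warning.
2. **Gap-adjacent removal** — the present day immediately before and
   after every run of missing days is removed. Gaps are defined against
   the observed-day reference, so the filter is idempotent: days removed
   by the filter itself do not become new gaps.
3. **Window and coverage** — days outside 10–305 are dropped; a lactation
   is kept only with ≥ 148 retained days (50% of the 296-day window).
   The coverage rule is applied last, to the fully filtered series.

The **predicted lactation curve** is a cubic P-spline (Eilers–Marx:
equally spaced knots extended beyond the data, fourth-order difference
penalty) with the penalty weight solved so the effective degrees of
freedom (trace of the hat matrix) equal 5. The fourth-order penalty makes
every cubic polynomial penalty-free, so polynomial trends are reproduced
without bias; the steep early-lactation rise of a strongly peaked curve
is beyond 5 df of flexibility and retains a small systematic residual
(order 0.1 kg for the shapes simulated here). Disturbance down-weighting
is iterative and deliberately simple, a pluggable stand-in for weighting
by assumed disturbance strength: after each fit, days with negative
residuals get weight `clip(1 − |r|/(3σ̂), 0.1, 1)` with `σ̂` the MAD
scale of the residuals; two refits are performed. This lets yield drops
pull the predicted curve down as little as possible.

## Genetic evaluation

Two univariate animal models per breed and trait:

* **P** (first lactation): `y = Xb + Zu + e`;
* **M** (all lactations, repeated records): `y = Xb + Zu + Wpe + e`,

with `u ~ N(0, G σ²_u)`, `pe ~ N(0, I σ²_pe)`, `e ~ N(0, I σ²_e)`, and
`G` the VanRaden genomic relationship matrix
`ZZ′ / (2Σ p_j(1−p_j))` on centered allele counts. `G` is blended with
the identity (`G* = 0.99 G + 0.01 I`) for invertibility. Fixed effects:
age at first calving (continuous, months), herd-year-season
(season = Mar–May, Jun–Aug, Sep–Nov, Dec–Feb), lactation-data
completeness class (≥90, 80–<90, 70–<80, 60–<70, 50–<60 %), and for M a
first-versus-higher lactation class. Levels with fewer than six animals
are excluded (iterated until stable).

REML: the single-record model profiles out `σ²_e` on the eigenbasis of
`G*` and maximizes over the variance ratio (bounded scalar search, exact
to the stated tolerance); the repeated-records model maximizes the
restricted log-likelihood over the three log-variances directly
(Nelder–Mead on Cholesky factorizations; variances floored at 1e−8 of
the phenotypic variance, boundary estimates flagged). Heritability is
`σ²_u / σ²_total`; repeatability adds `σ²_pe` to the numerator.

GEBVs are BLUPs from the mixed-model equations; prediction error
variances come from the inverse coefficient matrix, and reliability is
`r²_i = 1 − PEV_i / (g*_ii σ̂²_u)`. De-regression is the plain division
`û_i / r²_i` — a deliberate simplification (no parent-average removal),
stated rather than hidden — followed by z-standardization within group
(breed × lactation group × trait). Animals with non-positive reliability
are excluded with an audit entry.

## Population structure and LD

Classical (Torgerson) MDS of the `1 − IBS` distance matrix
(`IBS = mean (2 − |g_i − g_j|)/2`): double-center `−D²/2`,
eigendecompose, scale the top coordinates by the root eigenvalues.

LD between same-chromosome SNP pairs within **both** window constraints
(≤ 1,000 intervening SNPs AND ≤ 3,000 kb; the conjunctive reading matches
common tooling) is the squared allelic correlation
`r² = (p_AB − p_A p_B)² / (p_A p_a p_B p_b)`. The haplotype frequency
`p_AB` is counted directly when phase is available; otherwise it is
estimated by EM over the double-heterozygote cell (50 iterations,
tolerance 1e−10). The phase path is exact and is checked against a
brute-force counting oracle; the EM path agrees with it statistically
(not numerically — double heterozygotes are genuinely ambiguous at finite
sample size). Decay curves are distance-binned means; empty bins are
reported missing, never zero.

## GWAS

Each SNP is tested as a fixed effect in `y = μ + Xb + Zu + e` with
`u ~ N(0, G σ²_u)` on the Yang et al. GRM (standardized genotypes,
corrected diagonal). Null-model variance components are estimated once
per scan and held fixed for the per-SNP generalized least-squares Wald
tests (the standard MLMA approximation). Variants:

* **MLMA** — whole-genome GRM;
* **MLM-LOCO** — the GRM excludes the tested SNP's chromosome, with null
  components re-estimated per left-out chromosome;
* **MLM-LOCO + genome PCs** — LOCO plus the top 20 eigenvectors of the
  whole-genome GRM as fixed covariates against stratification.

Calibration is summarized by `λ_GC = median(χ²) / 0.455` (the 1-df
chi-square median). Model selection minimizes `|λ_GC − 1|` per breed and
rejects candidates with `λ_GC > 1.5` outright. Across-breed pooling uses
Fisher's method, `X² = −2 Σ ln p_i` on 2k df (k = 3 breeds); SNPs absent
in a breed are dropped with a count, zero p-values are clamped to the
smallest positive float with an audit entry. Pooled-scan inflation is
computed by converting pooled p-values back to 1-df equivalent
chi-squares before the median ratio. Significance tiers follow the
Bonferroni genome-wide level `0.05/N` and a fixed suggestive level
`5×10⁻⁵`.

## Synthetic data

No data are distributed with the analyses this package implements, so the
simulator is a first-class module that emulates the study design: three
breed clusters (default sizes 2,300 / 2,330 / 1,073 across 48
single-breed farms), repeated lactations, automatic-milking-system
records, and 50K-chip-scale genotypes.

**Genotypes.** Ancestral frequencies uniform on (0.1, 0.9); breed
frequencies Beta-distributed around them with the configured F_ST
(Balding–Nichols). Haplotypes come from a latent Gaussian AR(1) process
thresholded at the breed frequency quantile, so marginals are exactly
Bernoulli(p) while r² decays geometrically with marker separation
(persistence 0.9 by default, giving adjacent-SNP mean r² ≈ 0.2 at
50K-like spacing). Emitted SNPs respect a MAF floor (0.05).

**Phenotypes.** A Wood gamma curve `a·t^0.1·e^{−0.0022 t}` per
cow-lactation (scale ~N(20, 2) kg, +12% for later parities — a gently
peaked shape chosen so the 5-df spline tracks it well), Poisson
disturbance events with half-normal depths and exponential recovery, and
AR(1) daily noise. Two genetically controlled cow parameters:

* **log disturbance susceptibility** (polygenic + optional QTL) scales
  the cow's *entire* deviation process — event depths and residual noise
  alike. Because lag-1 autocorrelation is invariant to an overall scale,
  susceptibility moves the variance indicators without moving `r_auto`;
  this is what makes genuinely disjoint genetic architectures of the two
  indicator families constructible at all.
* **residual persistence** (the AR(1) coefficient, purely polygenic by
  default) drives `r_auto`.

The two parameters draw causal loci from disjoint SNP pools. Their
heritabilities are set exactly in-sample to the configured targets
(defaults 0.15 and 0.05, the reported range for these trait families);
the *indicator* heritabilities are attenuated below the parameter
heritabilities by measurement noise, as in real data. Perturbations act
multiplicatively (`base·exp(pert/base)`), keeping yields positive without
hard clipping — clipping would create flat runs with spurious
autocorrelation. Milkings are generated as milk accumulated at each day's
secretion rate between jittered milking times (2 or 3 per day), so the
overnight milking genuinely carries the previous evening's production and
the preprocessing split rule is its correct inverse. Missing cow-days and
whole-farm outage days are dropped at configured rates.

**What the simulator does not emulate:** real bovine genome maps and
chip ascertainment, selection and pedigree structure, seasonal and
management trends in yield, imputation error, and genetic correlations
between the susceptibility and persistence channels (set to zero by
design). Passing tests therefore demonstrate internal correctness and
calibration of the methods, not that real resilience indicators have any
particular architecture.

**Disturbance magnitudes are not published for the source herds;** the
defaults (rate 4/lactation, depth SD 5 kg, half-life 7 days, noise SD
1.5 kg) were chosen once so that indicator heritabilities land in the
reported 0.05–0.20 range and lactation curves look like AMS data.

## Validation experiments and problem sizes

The acceptance script and `tests/test_acceptance.py` run, with sizes
chosen to keep the full suite in the tens of minutes on one CPU:

* analytic constants: λ_GC denominator 0.455; 148-day coverage floor;
* null GWAS calibration at 2,000 individuals × 5,000 SNPs for all three
  variants (λ_GC within [0.9, 1.1], type-I error 0.05 ± 0.01);
* REML recovery of h² = 0.15 at n = 2,000 over five seeds (± 0.05);
* LD phase-counting oracle on 1,000 pairs (≤ 1e−6) and the printed
  frequency example (r² = 0.36 exactly);
* Fisher pooling: unit inputs pool to exactly 1; uniform inputs pool to
  uniform (KS p > 0.01 at 50,000 SNPs);
* MDS cluster recovery at F_ST = 0.1 (adjusted Rand = 1);
* the end-to-end disjoint-architecture run at demo scale (3 breeds × 300
  cows, 3 chromosomes × 1,000 SNPs, up to 3 lactations): the planted
  susceptibility QTL must reach the genome-wide tier (at the QTL or a SNP
  in r² > 0.8 with it) while the autocorrelation scan yields no
  genome-wide hit, in ≥ 8 of 10 seeds.

## Known limitations

* De-regression is plain division by reliability; pseudo-phenotypes of
  animals with very low reliability are noisy, as in any two-step GWAS on
  de-regressed proofs.
* The repeated-records REML uses a derivative-free search; it is robust
  at the scales used here but slower than an average-information scheme
  for very large record counts.
* The spline's disturbance down-weighting is a documented stand-in; the
  exact weighting of the original longitudinal-phenotyping literature is
  not reproduced.
* The 5-df spline biases predictions on steeply peaked curves' rises;
  `v_d` therefore has a small positive floor even for undisturbed cows.
* Reliabilities are PEV-based; software-specific reliability
  approximations used elsewhere may differ numerically.
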