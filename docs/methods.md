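# Methods

`biocharnet` implements the inference chain that links a biochar soil
amendment to reduced soil p-coumaric acid (p-CA): direct chemisorption of
the phenolic acid onto biochar, and an indirect microbial route in which the
amendment shifts soil properties, a keystone group of co-varying taxa, and
the community's aromatic-compound-degradation (ACD) function.  This note
documents the models, the numerical choices, and what the synthetic data do
and do not establish.

## Adsorption models

The adsorbed quantity is the batch mass balance `Q = (C0 − C)·V/M` (mg/g)
with the study geometry as defaults: 5 g biochar in 50 mL, kinetics at
C0 = 150 mg/L sampled every 15 min from 15 to 135 min, isotherms at
C0 ∈ {20, 40, 60, 120, 240, 360} mg/L.  All five models are estimated by
ordinary least squares on their classical linearised forms:

| model | linearisation | parameters |
|---|---|---|
| pseudo-second-order (PKE) | t/Qt on t | Qe = 1/slope, k = slope²/intercept |
| Elovich | Qt on ln t | a = intercept, b = slope |
| intra-particle diffusion | Qt on √t | kp = slope, c = intercept |
| Langmuir | Ce/Qe on Ce | Qmax = 1/slope, KL = slope/intercept |
| Freundlich | ln Qe on ln Ce | ln KF = intercept, 1/n = slope |

R² is reported on the linearised regression's own scale (the scale on which
the parameters are estimated), with a native-scale R² of the
back-transformed curve alongside; a nonlinear least-squares refinement
exists but is off by default, because the linearised estimates are the ones
the model equations imply.  Points with t ≤ 0 or Q ≤ 0 are excluded (the
PKE and Elovich transforms are undefined there); a non-positive PKE slope
is flagged as an invalid fit rather than raised.  Model comparison ranks by
R², alphabetical tie-break, ties flagged.

Simulated kinetic series carry their noise through the mass balance, so
`(C0 − Ct)·V/M` reproduces the noisy Qt exactly.  Simulated isotherm series
put measurement noise on the measured Qe while Ce keeps its equilibrium
value (solved from the isotherm jointly with the mass balance): pushing Qe
noise through the balance would multiply it by M/V = 100 g/L and swamp the
low-concentration points, which no laboratory protocol does — the
concentration and the adsorbed quantity are not measured through each other
at equilibrium.  The default kinetic truth (Qe = 1.2 mg/g, k = 0.1) sits
inside the mass-balance ceiling C0·V/M = 1.5 mg/g of the study geometry.

## Synthetic community

The generator emulates the incubation design: 9 no-biochar (NB) and 9
biochar (AB) samples, 150 OTUs — five modules of 40/30/25/20/15 members
plus a 20-OTU abundant background core — sequenced to 100,000 tags per
sample.  Counts follow a log-linear latent model: per-OTU log abundance is
`intercept + loading × module activity + noise`, passed through a softmax
and a multinomial draw per sample.

Two design choices depart from the obvious i.i.d. construction, both forced
by the small sample size:

* **Orthonormal in-sample factors.**  Module activities, a hub factor h and
  the trait residual are drawn as an orthonormal basis orthogonal to the
  intercept and to the NB/AB contrast (QR of a Gaussian matrix), scaled to
  unit sample variance.  With freely drawn activities at n = 18, pairs of
  "independent" modules correlate by chance up to |r| ≈ 0.55 and genuinely
  merge in any co-expression network; orthogonalisation makes the planted
  module structure hold in the realised sample, not just in expectation.
  Module-1 activity is then shifted by the treatment effect (default +2.0)
  along the group contrast.
* **Noise orthogonalised against trait-coupled directions.**  Each module
  OTU's idiosyncratic noise is projected off the factor space, and
  background noise off the trait-coupled directions.  Consequently a
  non-hub member's correlation with the trait (its MS) is set by its
  loading geometry rather than by sampling luck, and is structurally capped
  below the 0.6 hub threshold; the OTU–OTU clustering noise (which lives in
  the orthogonal complement, plus the multinomial counting layer and the
  compositional closure term) remains realistic.

The p-CA trait is `12.0 + trait_effect × (0.70·a₁ + 1.10·h) + 0.4·ε` mg/kg
with `trait_effect = −1`: the keystone module and, more strongly, its hub
taxa drive the trait down.  Four hub OTUs (two *Devosia*, two
*Nocardioides*, the genera being exclusive to them in the pool draw) load
on `0.96·a₁ + 0.28·h` with small noise and an elevated intercept.  The
background core has a high, stable intercept (3.0 ± 0.3 in log units),
which keeps the per-sample softmax normaliser — the compositional closure
term that correlates every OTU with every other — nearly constant.
Loadings are |N(1, 0.2)| clipped to [0.6, 1.4]; module noise sd is 0.5.

Design-phase calibration over 100 seeds: planted modules recovered with
ARI > 0.9 in 100/100 runs (minimum 0.911), keystone module anti-correlated
with the trait in 100/100, ≥ 80% keystone capture in 100/100, both hub
genera and no spurious hub genus in 97–100/100.

What the generator does **not** emulate: real phylogenetic correlation
structure, overdispersion beyond the log-normal/multinomial composition,
rare-taxon tails, richness differences between treatments (the reported
diversity increases are not planted), or sequencing artefacts.  Passing
tests establish that the chain recovers structure **of this planted kind**
at study scale — not that it would resolve the much weaker, messier
structure of real amplicon data.

The environment generator is independent: per-variable
Normal(mean × multiplier, cv × mean) truncated at zero, with the reported
treatment responses as default multipliers (+4.52% pH, +55.05% SOM,
−12.77% AN, −54.84% p-CA; others unchanged) and cv = 0.05 — the study gives
no within-group variances, so the cv is this package's choice.  In the
pipeline, the env table's p-CA column is replaced by the community-coupled
trait so that all community-facing statistics see one coherent trait; the
percent-change comparison of p-CA in a pipeline run therefore reflects the
community coupling, not the −54.84% multiplier (which `gen_env` reproduces
exactly at cv = 0).

## Community statistics

Alpha diversity wraps `skbio.diversity.alpha`: observed richness, Shannon
(natural log by default; base configurable), Simpson 1 − Σp², bias-corrected
Chao1, ACE with rare cutoff 10 (NaN where all rare taxa are singletons, a
case the estimator does not define), Pielou H/ln S and Good's coverage.
Beta diversity is Bray–Curtis on relative abundances; ordination is
classical PCoA (scikit-bio backend), with negative eigenvalues reported and
excluded from coordinates.  PERMANOVA is implemented in-package so the
permutation stream is explicitly seeded: pseudo-F from the within/between
partition of squared distances, `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)`;
its statistic is cross-checked against scikit-bio in the tests.  The
Bray–Curtis triangle inequality is not asserted anywhere — it can fail.

## Co-expression network

Profiles are ln(relative abundance × 10⁶ + 1), z-scored per OTU; sample
outlier screening (average-linkage Euclidean tree, keep the largest cluster
below a cut height) is available but off by default.  The network is
unsigned, `a = |cor|^β`.  The soft-threshold picker implements the
scale-free criterion (signed R² of the log–log degree-distribution
regression over ~10 bins, smallest power with fit > 0.9 and mean
connectivity > 10, else the best-fit power meeting the connectivity floor,
with a warning).  At 150 OTUs the mean connectivity at β = 6 is ~2, so the
paper-scale connectivity floor of 10 cannot co-exist with the fit rule at
desk scale; the pipeline therefore runs at the study's stated power β = 6
directly, and the picker's full table is available for inspection.

Topological overlap is the standard
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij)`.  Module
detection cuts the average-linkage dendrogram of 1 − TOM at 0.99 and then
refines branches recursively — a branch splits when both children hold at
least `min_module_size` (5) leaves and the relative dissimilarity gap
`(cross − within)/(1 − within)` exceeds 0.2, a scale-free criterion chosen
because raw TOM magnitudes vary enormously with β and signal strength.
Members whose mean within-module TOM falls below 0.4× the module median are
released to grey (they are almost always background taxa adopted by a
branch), and after eigen-taxon merging (correlation distance below 0.25,
recomputed until stable) grey OTUs with mean TOM above 0.8× a module's
within-mean are adopted back.  Both fractions were fixed in the same
design-phase calibration as the generator.

Eigen-taxa are first right singular vectors of the module submatrix, unit
variance, sign-oriented positive against the module mean profile (otherwise
module–trait signs are arbitrary).  Module–trait correlation is Pearson
with Student-t p (df = n − 2); the keystone module is the top-|r| module
with p < 0.05, else the top-|r| module is reported as a candidate with a
warning.  MS is |cor(OTU, trait)|, TM is cor(eigen-taxon, OTU), and the
role partition is hub (MS ≥ 0.6, |TM| ≥ 0.9), taxon hub (|TM| ≥ 0.9 only),
connector (MS ≥ 0.6 only), peripheral.  A genus is a hub genus when at
least one member OTU is a hub, ranked by max member MS·|TM|.

## Co-occurrence and function

Co-occurrence networks connect genera with Spearman |rho| ≥ 0.9 on
within-group relative abundances (the threshold is read as a correlation
bound — a p-value of 0.9 would be meaningless for edge selection); no
multiple-testing correction is applied, matching the source procedure.
Function annotation uses a simplified one-rule-per-line dialect
(`pattern<TAB>function,function`), pattern matched as a substring of any
lineage rank token; the bundled ~20-genus rule miniature covers
chemoheterotrophy, aerobic chemoheterotrophy, ACD and nitrification.  A
function's per-sample abundance is the summed relative abundance of its
carrier OTUs (full abundance per function, no splitting), by default
restricted to the keystone module's members but always relative to the
whole community.

## Mantel tests and group comparisons

Group comparisons run Shapiro–Wilk per group and Levene across groups;
pooled-variance t when Levene p ≥ 0.05, Welch otherwise, all two-sided.
The Mantel statistic is Pearson correlation of lower-triangle vectors
(Spearman via flag); the null permutes rows+columns of the second matrix
jointly, exhaustively over all n! relabellings when n ≤ 6, otherwise with
`p = (1 + hits)/(1 + n_perm)`, two-sided on |r|.  The Mantel grid pairs the
community Bray–Curtis matrix with per-variable Euclidean distances on
z-scores — the distance convention is this package's stated contract, since
the source does not specify one.

## PLS path modelling

Lohmöller estimation with the centroid inner scheme and mode-A outer
weights, the defaults of the reference R implementation; the binary
treatment indicator is standardised like any other column.  Single-indicator
blocks bypass the outer iteration.  Convergence is the maximum absolute
change of |weights| below 1e-6 within 100 iterations, else an error
carrying the last delta.  Paths are OLS of each endogenous latent score on
its predecessors; communality is the mean squared loading per block
(single-indicator blocks contribute 1); GoF = √(mean communality × mean
R²).  Indicator pruning removes |loading| ≤ 0.8 and refits until stable;
emptying a block that downstream paths require is an error.  Bootstrap
resamples rows with replacement and aligns each replicate's latent signs to
the base fit through the loading pattern before collecting paths — without
this, sign-indeterminate replicates inflate the intervals.

The default structure: Biochar → {Soil, p-CA}; Soil → {Diversity,
HubGenera}; {Diversity, HubGenera} → ACD; ACD → p-CA.  For parameter
recovery, `gen_sem_data` plants standardized paths by exact second-moment
construction: each structural residual is orthogonalised against all
previously generated columns and scaled so the sample covariances equal the
implied values exactly, making the standardized OLS (hence PLS) paths match
the planted truths to machine precision for any seed.  Two of the planted
defaults (0.866 for Biochar → Soil organic matter, −0.623 for the direct
Biochar → p-CA path) are the reported coefficients; the remaining values
are plausible fill-ins, since one reported coefficient (−0.0243) appears
three times in the source and is treated as a typographical duplication.

## Pipeline and problem sizes

`run_all` executes simulate → adsorption → community → co-expression →
network/function → environment statistics → path model, with per-stage
seeds spawned from one `SeedSequence`; summaries are JSON without
timestamps, so equal seeds give byte-identical output.  Default problem
sizes (150 OTUs, 18 samples, 999 permutations, 200 bootstrap replicates)
complete in a few seconds on one CPU; the acceptance script's calibration
loops (1,000 null replicates at 99 permutations each) run in under a
minute.  These sizes were chosen as the smallest at which every planted
property is comfortably resolved.

## Known limitations

* The dynamic tree cut is the simple branch-split variant, not the hybrid
  PAM-like algorithm of the reference implementation; on very shallow
  dendrograms the split margin of 0.2 may under-split.
* ACE is undefined (NaN) for samples whose rare taxa are all singletons.
* PERMANOVA permutes labels freely (no strata/blocks).
* The FAPROTAX-style rule dialect has no wildcards or negations.
* Reported-scale quantities that depend on the deposited sequencing data
  (absolute diversity changes, the five-module composition, the empirical
  Adonis R², the empirical GoF) are outside what synthetic data can
  reproduce; the pipeline reports its own computed values for these.
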