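# Methods

## Dynamical model and average controllability

The structural connectome of each subject is a symmetric matrix `W` of
fractional anisotropy (FA) edge weights in [0, 1] over 234 regions (220
cortical, 14 subcortical), zero diagonal. Missing connections are exact
zeros; a zero-weight edge contributes nothing to the dynamics, so "absent"
and "FA = 0" are deliberately not distinguished.

Neural activity is modelled as noise-free discrete-time linear dynamics
`x(t+1) = A x(t) + B u(t)` with `A = W / (1 + λ_max(W))`, where `λ_max` is
the largest eigenvalue of `W` (non-negative for non-negative symmetric
weights). The normalization makes the spectral radius
`λ_max / (1 + λ_max) < 1`, i.e. `A` is Schur stable, so the infinite-horizon
controllability Gramian with single-node input `B = e_i`,

    W_i = Σ_{k≥0} A^k e_i e_iᵀ (Aᵀ)^k,

converges. Average controllability of node i is `trace(W_i) ≥ 1`, with
equality exactly for isolated nodes (the k = 0 term contributes 1). This
normalization-plus-trace formulation is the standard one in the network
control literature on diffusion-MRI connectomes; alternatives (subtracting
the identity, finite horizons) are monotone transforms that would not change
sign patterns of the statistics, but they are not what this package
computes.

Three routes to the Gramian are implemented:

1. direct discrete Lyapunov solve `A X Aᵀ − X + B Bᵀ = 0`
   (`scipy.linalg.solve_discrete_lyapunov`), used by `gramian()`;
2. the truncated series with horizon `K` chosen so the tail bound
   `ρ^{2(K+1)}/(1 − ρ²) < 1e-10` holds (`gramian_series()`, also the
   automatic fallback if the solver fails);
3. for the batch path, the symmetric-`A` identity
   `trace(W_i) = [(I − A²)^{-1}]_{ii}`, one positive-definite solve per
   subject instead of 234 Lyapunov solves.

Routes are cross-checked against each other in the test suite and in the
reproduction script (maximum elementwise discrepancy on 200 random
10–50-node systems is ~1e-12, against a 1e-8 requirement), and against
closed forms summed by hand on the 2-node chain:
`W = diag(1/(1−a⁴), a²/(1−a⁴))`, `trace = 1/(1−a²)`, `a = w/(1+w)`.

System-level controllability is the unweighted arithmetic mean over member
nodes — size-normalized and the convention of the framework this model
follows; an empty system yields NaN, never a silent zero.

## Atlas and system assignment

Cortical regions are assigned to the seven canonical resting-state systems
(fixed order DMN, DA, FCN, LN, SMN, VN, VA) by the purity index: from a
table of per-region vertex-overlap counts, the winning system is the argmax
count and purity = max count / total count (including any "unassigned"
vertices). Ties break to the lowest index in the fixed ordering — no
convention exists in the literature, and a deterministic rule is required
for reproducibility. The 14 subcortical regions (bilateral thalamus,
caudate, putamen, pallidum, accumbens, hippocampus, amygdala) form the
eighth system unconditionally.

The repository ships a *synthetic* 234-row atlas and overlap table
(`atlas234_synthetic.tsv`, `overlap234_synthetic.tsv`): structurally
faithful (220 cortical + 14 subcortical, plausible region names and
system proportions, all eight systems non-empty) but not the actual
Lausanne 2008 label list, which is not redistributed here. A reduced
20-node atlas (16 cortical + 4 subcortical, same structural invariants
proportionally) backs fast tests and simulation replicates.

## Statistical battery

- **Primary GLM**, per system and per node:
  `AC ~ 1 + diagnosis + age + diagnosis×age + sex + education`, OLS, with
  diagnosis SCZ = 1/HC = 0, sex M = 1/F = 0, age in raw (uncentered) years.
  Centering would change the main-effect tests but not the interaction F,
  which is the quantity of interest. The interaction test is the 1-df
  partial F from dropping the term — identical to the squared t of its
  coefficient, and to a Type-III test for a 1-df term; p from F(1, n−6).
  Rank-deficient designs (e.g. a single-sex cohort) are rejected with the
  collinear column named.
- **FDR**: Benjamini–Hochberg step-up at q = 0.05, applied separately to
  the 8-system family and the 234-node family
  (`statsmodels.stats.multitest`). Raw-significant (p < 0.05) and
  FDR-significant flags are both always recorded, since follow-up
  conventions in this literature mix the two.
- **Trajectories**: for every target with a raw- or FDR-significant
  interaction, within-group partial correlation of AC with age controlling
  sex and education, by the residual method: Pearson r of OLS residuals,
  `t = r√((n−2−k)/(1−r²))` on n−2−k df, two-tailed. With no covariates this
  reduces exactly to the Pearson correlation.
- **Age-35 subgroups**: younger = age ≤ 35, older = age > 35. On the full
  cohort, a diagnosis×subgroup GLM; within each subgroup, a diagnosis×age
  GLM; sex and education covaried throughout; p-values deliberately
  uncorrected (the battery is restricted to targets already significant in
  the primary analysis and is explicitly heuristic).
- **Clinical correlations** (patients only): partial correlations of each
  followed-up target with DUP, GAF and the four PANSS scores, controlling
  age, sex and education; one FDR family over all target×measure pairs.
  DUP is analyzed untransformed by default despite its heavy skew — the
  primary description of this analysis does not transform it — with a
  `log_dup` flag for log(1+DUP).
- **Demographics**: pooled-variance two-sample t for age and education,
  Pearson chi-square *without* continuity correction for sex (the
  uncorrected statistic is what reproduces the reference value 0.01 from
  the 81/94 vs 71/84 counts; with Yates it would be ~0.00).

A note on the demographic worked examples: the reference t-values were
computed from raw data, while this package recomputes them from group
summaries printed at two decimals. Propagating that input rounding gives
t = 1.354 ± ~0.01 for age (reference prints 1.36) and |t| = 2.076 ± ~0.03
for education (reference prints 2.09); the chi-square reproduces exactly.
The tests assert agreement within those rounding bounds.

## Synthetic cohorts

`GeneratorConfig` defaults encode the study conditions: 175 patients / 155
controls; ages 16 + Gamma, truncated at 60, targeting means 28.7/27.0 and
SD ≈ 11 per group, giving the right-skewed distribution with roughly 75% of
subjects ≤ 35; exact observed sex counts (81/175, 71/155 male); education
N(11.61, 3.54)/N(12.41, 3.44) clipped to [0, 22]; PANSS and GAF normal with
the reported moments, clipped to scale ranges; DUP log-normal with
μ = 2.643, σ = 1.328 (mean 33.9, SD 74.6 months — the log-normal family is
an assumption, only the first two moments being known).

Connectomes are modular: within-system edge probability 0.7 vs 0.3
between, FA weights Beta(9, 11) (mean 0.45, SD 0.11 — typical white-matter
FA), one cohort-shared backbone per seed. Per subject, within-system edges
of system s are scaled by `1 + slope_group(s)·(age − 38) +
group_offset(s)·[SCZ]`, every present edge gets multiplicative noise
`1 + 0.05·N(0,1)` (5% edge-level FA variability, a realistic test-retest
scale), and weights are clamped to [0.05, 0.95] (a warning fires if an
effect spec clamps more than 20% of edges). Age is centered at 38 — the
midpoint of the 16–60 range — inside the generator only, so slopes and
offsets are interpretable; the analysis never sees this. Effects are
injected at the *edge-weight* level, never into controllability directly,
so recovery exercises the real stabilization → Gramian → GLM chain.

**Calibration of the injected slope.** The recovery study's slope was fixed
by calibration runs: −0.004/yr gave ~80% FDR detection at n = 175/155 on
the 20-node atlas (borderline), −0.005/yr gives ~90% detection with a
moderate trajectory contrast (HC partial r ≈ −0.4 to −0.6, patients flat).
The calibrated default is −0.005/yr with edge noise SD 0.05.

**Spillover through normalization.** Injection is perfectly local at the
edge level, but the shared normalization `1 + λ_max` couples systems: a
within-system decline in one system lowers `λ_max`, which *raises* the
normalized coupling — hence the controllability — of untouched systems.
On the 20-node atlas, a bilateral subcortical decline (r ≈ −0.84 with age)
induces an opposite-signed DMN trend of r ≈ +0.2. This is model physics,
not a generator artifact; it is weaker on the full 234-node atlas (the
injected block is a smaller share of the spectrum) and it cannot mimic a
same-signed false finding. Tests assert edge-level locality strictly and
bound the spillover at half the injected magnitude with opposite sign.

**What the generator does not emulate:** tractography and its biases,
scanner/site effects, FA spatial autocorrelation, non-linear aging,
symptom–connectome coupling (clinical scores are independent of the
connectomes unless a test injects a dependency). Passing recovery tests
therefore show the *pipeline* recovers known effects under its own
assumptions — they are not evidence about real cohorts.

## Problem sizes and determinism

The test suite and reproduction script run the replicate studies at the
reduced 20-node scale — 100 recovery replicates at n = 330, 1000 null
replicates at n = 100 — sizes chosen so the full battery of checks
completes in a few minutes on one core while leaving the Monte-Carlo error
on the measured rates near one percentage point; the full 234-node path is
exercised end-to-end at smaller cohort sizes. All randomness flows from
explicit seeds through `numpy.random.SeedSequence` (per-subject child
seeds), so every dataset, analysis and report is a pure function of
(config, effect spec, seed); regeneration is byte-identical and verified
by manifest SHA-256 hashes.

## Known limitations

- The Gramian formulation is pinned to one (standard) normalization;
  variants in the literature differ by monotone transforms.
- The purity index assumes vertex counts; if real overlap tables use areas
  or voxel volumes the ratio semantics are unchanged.
- System aggregation is the unweighted node mean; strength-weighted
  aggregation is not implemented.
- OLS assumes homoscedastic errors; controllability distributions are
  mildly right-skewed, which the rank_transform option can blunt, at the
  price of departing from the primary specification (default off).
- The subgroup battery inherits the usual caveats of median-style splits
  (reduced power, boundary sensitivity at exactly 35 years).
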