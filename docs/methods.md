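# Methods

This note documents the models implemented in `acidscreen`, the default
parameters and their rationale, what the synthetic generators do and do
not emulate, and the numerical choices that matter for reproducing the
results.

## 1. Screen simulator (`simdata.simulate_screen`)

The generator emulates a pooled CRISPR knockout viability screen run in
parallel at three extracellular pH levels and sequenced at two
timepoints.

**Library and T0.** `n_genes` genes (default 2000) with
`guides_per_gene` guides (default 4). Initial guide abundances are
drawn log-normally (log-sd `t0_skew = 0.5`) around a mean
representation of 675 cells per guide, emulating the uneven coverage of
a transduced library at low multiplicity of infection. T0 counts are
sequenced from these abundances.

**Growth phase.** Each gene is assigned one of four classes by exact
largest-remainder allocation of the class fractions (default: neutral
0.80, core-essential 0.10, acid-essential 0.05, acid-dispensable
0.05), followed by a seeded permutation. Cells carrying a guide grow
exponentially for 11 days at per-day rates

    rate(guide, cond) = base_rate(cond) · multiplier(class, cond)^efficacy

with base rates 0.69 / 0.48 / 0.35 per day at pHe 7.4 / 6.9 / 6.63
(doubling roughly daily at physiological pH, visibly slower under
acid), class multipliers (1.0 everywhere for neutral; 0.5 everywhere
for core-essential; 1.0 / 0.85 / 0.7 across the three pH levels for
acid-essential; 1.0 / 1.15 / 1.3 for acid-dispensable) and a per-guide
knockout efficacy drawn uniformly on [0.6, 1] — not every guide cuts
equally well.

**Bottleneck.** At day 5 each condition is passaged: 3×10^6 cells are
reseeded by a multinomial draw over guides, emulating the
representation loss of a split.

**Sequencing.** Endpoint (and T0) counts are gamma–Poisson (negative
binomial, dispersion 0.1 — a typical amplicon-sequencing
overdispersion) at a mean depth of `depth` reads per guide (default
500). Sample columns are named `T0_r<i>` and `T11_ph<cond>_r<i>`. All
randomness derives from `numpy` `SeedSequence.spawn` sub-streams, so
adding replicates or conditions does not perturb the others.

**Not emulated:** guide-sequence-specific efficacy, off-target cutting,
copy-number artefacts, PCR jackpotting beyond NB overdispersion, cell
death kinetics distinct from slowed growth, and inter-replicate
biological batch effects (replicates differ only by sampling noise).

## 2. Differential-essentiality scorer (`screenz`)

The scorer implements a normZ-style pipeline.

1. **Normalisation.** Each sample is scaled to a common depth:
   `norm = (count + p) · S / (total + p·n_guides)` with pseudocount
   `p = 5` and scale `S = 1e7`. The pseudocount stabilises
   low-count guides; because it is added before scaling, normZ is only
   *approximately* invariant to multiplying one sample's counts by a
   constant — at depth 500, a 3× depth change moves normZ by < 0.05,
   and gene ranks are essentially unchanged (rank correlation
   > 0.999). The tests assert this approximate invariance explicitly.
2. **Fold changes.** Per-replicate log2(treated/control) per guide,
   with treated and control replicates paired by replicate index.
3. **Empirical-Bayes guide noise.** Guides are sorted by decreasing
   control readcount (ties broken by guide id for determinism) and the
   fold-change standard deviation is estimated in a sliding window of
   `half_window = 500` neighbours on each side. A running maximum
   enforces that the estimate is non-increasing in readcount (low-count
   guides may not look less noisy than high-count ones), and a floor of
   1e-6 guards degenerate all-identical windows. Guide Z = fc / sd.
4. **Gene scores.** Per gene, sumZ over all guide×replicate
   observations; normZ = sumZ / sqrt(n_obs), then robustly standardised
   by the median and 1.4826·MAD across genes (falling back to a scale
   of 1 if the MAD is zero, e.g. on degenerate data). Directional
   p-values come from the normal tail; depleted and enriched FDRs are
   computed separately by Benjamini–Hochberg (`statsmodels`
   `multipletests`). Hits are genes with FDR below the cutoff (default
   0.1); each hit set records its `boundary_normZ`, the least extreme
   score still called.
5. **Overlaps and overrepresentation.** Set overlaps are plain
   intersections. The one-sided overrepresentation p-value for a hit
   set against an annotated set within a finite universe is the
   hypergeometric survival function, which is mathematically identical
   to the one-sided Fisher exact test; the test suite checks it against
   an exact integer tail sum over all small 2×2 tables.

## 3. Biphasic growth model (`acidfit`)

Growth versus pHe is the product of an acid-activated and an
acid-inhibited Hill term in the proton concentration h = 10^(−pH):

    G(pH) = G_max · h^n_act/(h^n_act + K^n_act) · Q^n_inh/(h^n_inh + Q^n_inh)

Parameters: `G_max` (absorbance units), midpoints `K`, `Q` in mol/L
(reported as pK_act = −log10 K, pK_inh = −log10 Q) and Hill
cooperativities `n_act`, `n_inh` (dimensionless). The factors are
evaluated through `expit` of a logit-space expression, which is exact
and overflow-free for any pH. With pK_act > pK_inh the curve has an
interior optimum; for n_act = n_inh = 1 the optimum is analytically
(pK_act + pK_inh)/2, which the tests use as an oracle. `pH_opt` is
found by bounded scalar minimisation (xatol 1e-10); **pH50** is the
acid-side root of G(pH) = G(pH_opt)/2 by Brent's method. If the
half-growth point lies below the search floor (pH 5.0, the edge of
plausible culture conditions), pH50 is censored at the floor and
flagged.

**Fitting.** Nonlinear least squares (`scipy.optimize.least_squares`)
in θ = (log G_max, pK_act, log n_act, pK_inh, log n_inh), with pK
bounds [5, 9] and cooperativity bounds [0.3, 8]. The problem is
multi-modal, so nine deterministic starts are used (a 3×3 grid of
pK_act ∈ {7.4, 8.1, 8.8} × pK_inh ∈ {5.6, 6.4, 7.2}) at a tight
tolerance (1e-14); the best residual wins. Bootstrap refits instead
warm-start from the full-data fit at tolerance 1e-10, which is ~10×
faster and empirically lands on the same basin.

**Comparison.** `compare_pH50` case-resamples wells within each group
(default 200 resamples), refits, and reports the percentile 95% CI of
the pH50 difference. If more than 20% of resample fits are censored at
the floor, the comparison is flagged unreliable.

**Accuracy.** Noiseless six-level, three-replicate plates recover all
five parameters to better than 1%. With 5% multiplicative noise the
pH50 RMSE over 100 plates is ≈ 0.021 pH units with |bias| < 0.01. Note
that the pH50 of a curve whose half-growth point lies below the lowest
assayed pH is an extrapolation and is estimated far less precisely —
the demo therefore uses a wild-type curve whose pH50 (≈ 6.48) sits
inside the assayed range (6.50–7.70).

## 4. Media and probe chemistry (`chemlab`)

- **Henderson–Hasselbalch.** pH = 6.1 + log10([HCO3−] / (0.0307 ·
  %CO2/100 · (760 − 47))), with [HCO3−] in mM, the CO2 solubility
  0.0307 mM/mmHg at 37 °C, and a water vapour pressure of 47 mmHg at
  atmospheric 760 mmHg. 22 mM / 5% CO2 gives pH 7.40. The inverse
  (`hh_hco3`) is exact.
- **Media series.** `bicarb_series` builds iso-osmolar
  NaHCO3/NaCl media summing to 44 mM so that only pH, not osmolarity,
  varies across the series.
- **Buffering capacity.** β(pH) = Σ 2.303 · C · Ka·h/(Ka+h)² over the
  closed buffers (HEPES pKa 7.5, MES pKa 6.1, both 10 mM when present)
  plus the open-system bicarbonate term 2.303·[HCO3−], in mM per pH
  unit.
- **Ratiometric pH dye.** R(pH) = (R_acid + R_base·10^(pH−pKa)) /
  (1 + 10^(pH−pKa)); the inverse returns (pH, censored) with censoring
  outside the dynamic range. Calibration fits (R_acid, R_base, pKa) by
  least squares with pKa bounded in [5, 9] and errors if the data do
  not span both plateaus.
- **Oxygen.** Stern–Volmer: [O2] = (F0/F − 1)/Ksv.
- **Photometry simulator.** Forward-Euler integration of
  dpH/dt = −J_H(pH)/β(pH) with a glycolytic acid flux that falls at low
  pH (product inhibition), and dO2/dt = −OCR floored at zero. Step size
  is user-controlled; the tests verify convergence under step halving.

## 5. Pipeline and reproducibility

`pipeline.run_demo` chains simulate → score (both acid contrasts) →
hits/Venn/overrepresentation → plates → fits → bootstrap comparison →
summary, tagging any failure with its stage name. All outputs are
written with fixed float formats and sorted keys; provenance records
the package version, seed, a config hash (excluding the output
location) and content digests of every written file — deliberately no
timestamps, so a re-run with the same seed is byte-identical, which the
tests assert.

Problem sizes in the tests and the acceptance script (2000 genes × 4
guides at depth 500; 50 null screens; 100 noisy plates; 10,000
permutation draws) were chosen to keep the full suite under a minute
of scoring time on one CPU while leaving the Monte-Carlo standard
errors well below the asserted tolerances.

## 6. Limitations

- The scorer assumes paired replicates and a single endpoint contrast;
  time-course modelling is out of scope.
- The empirical-Bayes window uses a fixed half-width (500); very small
  libraries fall back to a near-global variance estimate.
- Depth-scaling invariance of normZ is approximate (see §2).
- pH50 below the assayed pH range is an extrapolation; the bootstrap
  CI widens accordingly and censoring at pH 5.0 is reported, not
  hidden.
- The simulators are calibrated to be *plausible*, not to reproduce any
  particular dataset; their class multipliers and noise levels are
  documented defaults, all overridable.
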