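# Methods

## Scope and model

The package models the toxicity of binary metal-oxide nanoparticles
(MONPs) to zebrafish, expressed as percentage inhibition of the hatching
enzyme ZHE1 (%EI_zebrafish), using ordinary least squares on a small pool
of interpretable descriptors. Nothing in the pipeline requires structure
files or quantum chemistry: every input is a chemical formula plus
tabulated element constants, which is the point of the approach — a
screening-grade model whose descriptors can be computed by hand.

## Periodic-table descriptors

For an oxide M_aO_b with metal atomic number Z, outermost-shell electron
count Zᵛ and period PN:

* generation 1 (7): MW, N_metal, N_oxy, χ (Pauling), Σχ = χ·N_metal,
  Σχ/nO, and the charge-balance oxidation number χ_ox = 2·N_oxy/N_metal
  (kept as an exact rational; mixed-valence oxides such as Co₃O₄ get the
  average state 8/3);
* generation 2 (16): λ = (Z − Zᵛ)/Zᵛ (core-to-valence electron ratio),
  μ = 1/(PN − 1), α = λ·μ, Σα = α·N_metal + 0.33·N_oxy and its square
  (molecular bulk), ε_metal = −α + 0.3·Zᵛ, the oxygen constant
  ε_oxy = 1.47, Σε, Σε/N and its square, plus Z, Zᵛ, PN and V_metal;
* generation 3 (5): atomic radius a₀ (pm), Shannon crystal ionic radius
  (pm, coordination VI, resolved to the tabulated state nearest the
  oxide's oxidation number), elemental density (g/cm³), electron affinity
  and first ionization energy (eV).

Conventions that required a decision:

* **Zᵛ ("paper_compat" profile)** is the electron count of the outermost
  occupied *shell* of the ground-state atom: the ns count for s- and
  d-block metals (so Cr, Cu, Nb, Mo, Ru, Rh, Ag, Pt, Au → 1; most others
  → 2), ns+np for p-block metals (Pb → 4, Bi → 5), and 18 for Pd (its
  outermost occupied shell is n = 4 with 4s²4p⁶4d¹⁰). Vanadium carries a
  stored override (Zᵛ = 5). This is the unique convention under which the
  published external (Σα)² column reproduces for 34 of its 35 rows; the
  one exception, IrO₂ (printed 84.46, computed 66.59 for every plausible
  integer Zᵛ), is treated as a data-entry anomaly and excluded from golden
  comparisons. A "standard" group-valence profile is provided for
  comparison only.
* **0.33, not 1/3** in Σα_oxy: the published reference values (MgO
  8.0089 → 8.01) fix the literal constant.
* **V_metal** defaults to the charge-balance valence (= χ_ox); it enters
  neither reference equation, so the choice is inert for reproduction.
* Element constants live in one versioned CSV
  (`src/nanoqrastr/data/element_properties.csv`, curated from standard
  CRC/Shannon/NIST tables, one source note per row). Missing constants
  raise; they are never silently zero.

## Read-across (RASTR) descriptors

Features are standardized to training mean 0 / SD 1 (constant features
are rejected by name). Similarity between standardized rows is a kernel
of the Euclidean distance d: Laplacian exp(−γd) (suffix "LK") or Gaussian
exp(−γd²), default γ = 1/p. Each query's k = 10 most similar training
compounds (ties broken by source index; training compounds never see
themselves) yield 15 descriptors: the similarity-weighted read-across
prediction RA_pred = Σsᵢyᵢ/Σsᵢ, the weighted response SD about it
(SD_Activity), SE = SD_Activity/√k, CVact, the similarity profile
statistics AvgSim, SD_Similarity, CVsim = SD_Similarity/AvgSim, the
positive/negative class split at the training-mean response (MaxPos,
MaxNeg, AbsDiff, PosAvgSim, NegAvgSim) and the concordance sign
gm = ±1 with its products gmAvgSim and gmSD_Similarity. The originating
read-across software does not publish closed forms; these definitions are
tool-compatible reconstructions, config-exposed so alternates can be
swapped without touching callers. CVsim is not bounded by 1 (quoted
training values above 1 confirm this behaviour).

## Modeling and validation

Best-subset selection enumerates all C(p, m) descriptor subsets (m ≤ 5),
discards any subset with pairwise |Pearson r| > 0.90 (configurable) and
ranks survivors by LOO Q², ties by R², then lexicographic names; an
LOO-MAE criterion is available. OLS fits (statsmodels) report
coefficients with SEs from the unbiased residual variance. LOO Q² uses
PRESS with the full-training-mean denominator; PRESS is computed both by
explicit refits and the hat-matrix identity eᵢ/(1 − hᵢᵢ) and the two must
agree to 1e−8 relative. External predictivity uses Q²F1 (training-mean
denominator) and Q²F2 (test-mean; always ≤ Q²F1). Golbraikh–Tropsha
checks use the literature default thresholds (r² > 0.6, through-origin
r₀² gap < 0.1 in at least one direction, slope k or k′ in [0.85, 1.15],
|r₀² − r₀′²| < 0.3) plus an explicit positive-correlation flag, since r²
alone cannot distinguish anti-correlated predictions. Y-randomization
permutes the response without replacement with a seeded PRNG, refits, and
reports per-iteration and mean R²/Q²; means below 0.5 indicate the model
is not a chance correlation. The train/test split scores compounds on the
first principal component of the standardized descriptor matrix and sends
every ⌈1/test_fraction⌉-th compound in rank order to the test set
(n = 24 at 1/3 gives the reference 16/8 shape); an explicit index list
can override it.

## Applicability domain and reliability

Leverage AD: h_q = x_q(XᵀX)⁻¹x_qᵀ with intercept column, critical value
h* = 3p′/n, residuals standardized by the training SEE for the Williams
table. Standardization AD: a query is outside only if max|z| > 3 strictly
AND mean|z| + 1.28·SD(|z|) > 3 — one extreme descriptor in an otherwise
central compound does not eject it. The reliability grade combines (1)
the mean absolute LOO error over the query's 10 most similar training
compounds (pass if ≤ 1.5× the overall training LOO MAE), (2) the
standardization-AD verdict, and (3) proximity of the prediction to the
training response mean (pass if within 2 SD of the training response):
good = all pass; moderate = AD passes and exactly one other fails;
unreliable otherwise. All cutoffs are keyword arguments with these
defaults; the fusion rule is a package design choice, since only the
three criteria themselves are specified upstream.

## Reproduction of the published equations

The two reference equations and the 35-row external table ship as
checksummed fixtures. The read-across equation's (Σα)² coefficient is
stored as +0.17 although one typeset rendering shows a minus sign: only
the positive sign reproduces the external table (BaO: −2.01 + 0.17·32.83
+ 5.10·9.87 − 10.93·0.58 = 47.57 vs printed 47.63; the negative sign
gives 36.41) and matches the accompanying description of a positive
toxicity contribution.

Because all printed numbers carry two decimals, reproduction has a
precision floor. With the rounded coefficients, predictions for
small-(Σα)² compounds agree to about ±0.1. OLS of the printed predictions
on the printed descriptor triples recovers near-unrounded coefficients
(intercept −1.980, +0.1739, +5.088, −10.874) and tracks every row to
better than 0.08 %EI — but not to ±0.005, and no method can: the printed
descriptors are themselves rounded, so even the true coefficients would
leave residuals up to ≈0.005·(0.17 + 5.10 + 10.93) ≈ 0.08. The test suite
records this bound; the strict printed-precision assertion in the
acceptance tests documents the gap rather than papering over it.

The published training-set statistics (R² = 0.81, Q²LOO = 0.70,
Q²F1 = 0.76 for the read-across model; the Y-randomization means; the
AD status column derivation) require the unpublished experimental
training table and are therefore *not* asserted; the eight training
responses quoted in the narrative ship as a non-authoritative reference
CSV. In their place the suite checks statistical identities and
parameter-recovery properties on synthetic data (below).

## Synthetic data

`synth_dataset` generates small regression problems matching the study's
scale (defaults n = 24, p = 5; tests use n up to 50): standardized
features — abstract Gaussian draws or real descriptor rows sampled from
oxide formulas — with response y = β₀ + Xβ + N(0, σ), σ defaulting to
1 response unit, and the ground truth returned for recovery tests. It
emulates the dimensionality and noise level of small nano-QSAR datasets,
not their descriptor collinearity structure or experimental error
heteroscedasticity; green property tests therefore certify the machinery
(identities, coverage, subset recovery at high signal-to-noise), not
field performance on real MONP data.

## Numerical choices and limitations

Double precision throughout; comparisons against printed values use
half-ulp-of-print tolerance (±0.005 at two decimals). Similarity ties
break by source index; PCA scores get a deterministic sign convention so
row order cannot flip the split. Degenerate inputs (period-1 metal,
constant feature, singular design, zero test variance, < 2 neighbours)
raise typed errors naming the offender. Known limitations: binary oxides
only (no ternary/doped/coated particles), no particle-size or surface
descriptors, OLS uncertainty only, and the read-across descriptor
definitions are reconstructions — models built on them are internally
consistent but may differ numerically from the original tool's output.
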