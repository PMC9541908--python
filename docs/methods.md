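# Methods

## Effect sizes

All effects are Hedges' *d*: the standardized mean difference between two
tactic groups, multiplied by the small-sample factor J = 1 − 3/(4·df − 1)
with df = n1 + n2 − 2, with large-sample sampling variance

    var(d) = (n1 + n2)/(n1 n2) + d² / (2 (n1 + n2)).

Conversion routes implemented, each tagged in the output metadata:

* **Group summaries** (means, SDs or SEs, n per tactic); SEs are converted to
  SDs by sd = se·√n before pooling.  A zero pooled SD with unequal means is
  an error (the effect is undefined, not infinite).
* **Two-sample t**: d = t·√(1/n1 + 1/n2), then J.  Exactly round-trips the
  summary route when t is computed from the same summaries.
* **Mann–Whitney U** via the normal approximation without continuity
  correction: z = (U − n1n2/2)/√(n1n2(n1+n2+1)/12), r = z/√N,
  d = 2r/√(1 − r²), then J.  The chain is not uniquely fixed by convention;
  this is the simplest defensible one and the `conversion` tag makes such
  rows identifiable downstream.
* **Paired t** with unreported pair correlation: d = t/√n,
  var = 1/n + d²/(2n), no J (the appropriate df is unknown); rows flagged.
* **Partial η²** (from the ANCOVA route): Cohen's d = 2·√(η²/(1−η²)), signed
  by the adjusted group difference, then J.

In every route the variance is evaluated at the J-corrected d.  Reported
non-significant results lacking a direction are entered as d = 0 with
variance (n1+n2)/(n1n2) — the sample-size part only, so the row still
carries weight — and flagged so sensitivity fits can drop them.

Signs follow the sperm-competition convention: positive when the tactic
facing the higher sperm-competition risk (or investing less pre-mating) has
the larger value.  `apply_direction` is an involution and never touches |d|
or the variance.

## GSI vs ANCOVA

From one raw table of (tactic, body mass, testes mass):

* the **GSI route** computes 100·testes/(body − testes) per individual and a
  plain two-group Hedges' d;
* the **ANCOVA route** fits testes ~ soma + tactic (+ soma×tactic), drops
  the interaction when p ≥ α (α = 0.05; the analysis-wide convention),
  computes partial η² for tactic with the tactic sum of squares taken after
  the soma covariate (sequential/Type-II for this two-predictor model), and
  converts to a signed d.  Slope-heterogeneous tables (interaction p < α)
  are flagged but the effect is still taken from the common-slope model.

Masses are analysed on the raw scale, matching how such ANCOVAs are run in
the primary literature; GSI only corrects for body size under isometry, so
with allometric slope b < 1 GSI ∝ body^(b−1) rises for the smaller morph and
the GSI route invents a tactic difference where none exists.  The package's
simulations show this clearly: at b = 0.5 with two-fold size dimorphism and
no true difference, mean d_GSI ≈ 2.7 while the ANCOVA stays near zero.

A known subtlety, documented because it is visible in the simulations: the
ANCOVA route is itself not exactly unbiased under this generative model.
Using soma = body − testes as the covariate puts the testes measurement
noise on both sides of the regression, and a straight line fitted to a
power-law curve across well-separated body-size clusters absorbs curvature
into the group term.  Together these give the null ANCOVA d a small
systematic offset (≈ −0.15 under the default simulation settings, an order
of magnitude smaller than the GSI artefact it is diagnosing).

## The multilevel model

For k effects y with sampling variances v:

    Sigma(θ) = σ²_phylo Z_A A Z_Aᵀ + σ²_species Z_s Z_sᵀ + σ²_study Z_t Z_tᵀ
             + σ²_obs I [+ σ²_exper Z_e Z_eᵀ] + V

* **A** comes from the tree: prune to the species present, set every branch
  length to 1, make ultrametric by Grafen's rule (node height
  ∝ (descendant tips − 1)^ρ_G, ρ_G = 1 by default, normalized to unit root
  height), then correlation(i,j) = shared root-to-MRCA path / total depth.
  This matrix has unit diagonal exactly and is PSD by construction.
* **V** is diagonal v_i with ρ·√(v_i v_j) between effects from the same
  experiment (same sample of males).  ρ defaults to 0.5 — the halfway
  convention when trait correlations are unreported — with 0.25/0.75 refits
  in the sensitivity suite.  An optional experiment-level random intercept
  can be added on top.
* Phylogeny and species are separate random effects over the same species
  index, distinguished only by A vs I.  This is deliberately faithful to the
  four-factor model but the split is weakly identified — their sum is
  estimated much better than either part, which matters for interval
  coverage (below).

**Estimation.** REML.  The restricted likelihood is optimized by Nelder–Mead
on log σ² (one moment-based start by default, `n_restarts` adds randomized
starts), then polished by L-BFGS-B on the natural scale with a zero lower
bound so boundary components land exactly at 0.  On shared fixtures the
optimum matches the reference R implementation (metafor::rma.mv) to ~1e-6 in
β, SE and σ², and matches a brute-force grid search on small problems.  β is
GLS at θ̂; intervals are normal Wald (z), the toolchain default in this
literature; `use_t=True` switches to t/F references with k − p df.
"Significant" always means the 95% CI excludes zero.

**Reported statistics.**

* I² with the typical sampling variance
  s² = ((k−1)Σw)/((Σw)² − Σw²), w = 1/v; per-level
  I²_l = 100·σ²_l/(Σσ² + s²); the partition sums to the total by
  construction.
* Q_M: Wald chi-square on the moderator coefficients (intercept excluded),
  df = number of tested coefficients.  The reference distribution is noted
  in the output; see calibration below.
* Marginal R² = var(Xβ̂)/(var(Xβ̂) + Σσ²) with the population variance of
  the fitted values.
* Per-level means for categorical moderators come from a refit without
  intercept; levels with fewer than 5 effects are excluded from
  meta-regressions (configurable).
* Sneaker frequency enters as a proportion in [0,1]; the quadratic model
  (freq + freq²) is fitted first and its curvature term z-tested, the linear
  model alongside.
* Bias diagnostics are literally one-moderator meta-regressions: covariate
  1/SE (funnel asymmetry / small-study effect) or mean-centred publication
  year (time-lag); centring stabilizes the intercept and cannot change the
  slope.

## Synthetic data

The generator draws from exactly the model above: a Yule tree over
`n_species`, species effects ~ MVN(0, σ²_phylo A) plus independent species,
study and observation effects, within-experiment-correlated sampling errors
with v_i ~ U(0.05, 0.5), and species-level moderators (taxonomic group,
fertilisation mode, tactic type, sneaker frequency ~ Beta(2,5)) plus
per-effect trait categories and measurement labels.  Default design scale
follows the corpus the method targets: 67 species, 1–2 studies per species,
1–4 effects per study (≈ 92 studies / 251 effects), grand mean β = 0.4 and
components (0.2, 0.1, 0.1, 0.05) for (phylogeny, species, study,
observation).  Raw allometry tables follow log(testes) = log a + b·log(body)
+ noise, defaults b = 0.5, 2× body dimorphism, 30 individuals per tactic,
10% multiplicative noise and ~15% within-tactic body-size spread — typical
morphometric magnitudes.  The directionless-zero and small-study censoring
mechanisms are available as switches (off by default) because they are
data-handling artefacts, not part of the generative model.

What passing simulations do **not** show about real data: the generator's
effects are exactly normal with known v_i, moderators are balanced and
missingness-free, and within-experiment correlation is exactly ρ.  Real
corpora violate all of these; results here certify the machinery, not the
biology.

## Calibration notes (computed by the test suite / acceptance script)

* With all components pinned to zero the pooled estimate equals the
  inverse-variance weighted mean to 1e-10 (exact GLS reduction).
* At the corpus scale (k = 300) the pooled-mean estimate is essentially
  median-unbiased (median relative error ≲ 10%) and component medians are
  within ~15% of truth.
* The z-Wald CI of the pooled mean under-covers (≈ 86–92% instead of 95%):
  with components fixed at truth coverage is ~97%, so the deficit is the
  plug-in cost of the weakly identified phylogeny/species split — when
  σ²_phylo collapses toward zero the SE of the mean is understated.
* The chi-square Q_M is mildly liberal at k = 60 (≈ 6–8% at nominal 5%);
  with true components it is nominal (~5%), so this too is plug-in cost.
  `use_t=True` shrinks it substantially; the chi-square default is kept for
  fidelity to standard practice.

## Degenerate inputs and numerical choices

Zero pooled SD with unequal means, U outside [0, n1n2], η² ≥ 1, fewer than
2 (GSI) or 3 (ANCOVA) individuals per tactic, paired differences with zero
variance, single-level moderators, constant precision or a single
publication year all raise explicit errors rather than returning numbers.
Non-ultrametric trees are rejected by the VCV constructor (tolerance 1e-8
relative).  Cholesky failures inside the likelihood return a large penalty
so the optimizer retreats; a non-finite optimum raises.  Variance
components may estimate to exactly 0 (no collapsing of singleton levels).

## Known limitations

No multi-moderator joint models, robust variance estimation, Bayesian
estimation, trim-and-fill/selection models, or SMA allometry fitting.  The
paired-t fallback ignores the pair correlation.  Profile-likelihood or
parametric-bootstrap intervals for β would repair the coverage deficit noted
above but are out of scope.
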