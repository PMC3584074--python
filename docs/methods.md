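# Methods

## Model definitions

**BPNM.** Resources carry one position `n_j ∈ [0,1]` on a latent niche
axis; consumers carry a center `c_i ∈ [0,1]` and width `r_i ∈ (0, 2]`.
The pair interaction probability is the generalized-Gaussian kernel
`p_max · exp(−(|n_j − c_i|/(r_i/2))^g)` with two global parameters: the
cutoff-shape exponent `g ∈ [1, 20]` and the peak probability
`p_max ∈ (0, 1]`.  `g` and `p_max` are treated as single global
parameters, giving the parameter count `k = S_R + 2·S_C + 2`.  The width
cap of 2 lets a niche span the whole axis; the `g` cap avoids numerically
flat plateaus.  All probabilities are clamped to `[1e−10, 1 − 1e−10]`
so the Bernoulli log-likelihood is finite on every input — in particular
for cascade-forbidden pairs that coincide with observed links, whose
"probability zero" is represented by the clamp floor.

**Cascade.** Order parameters `phi_i` (consumers) and `psi_j`
(resources) on [0,1]; a pair is possible iff `psi_j < phi_i`.  All `L_p`
possible pairs share probability `L/L_p` so the expected link count
equals the observed one.  The likelihood depends on the parameters only
through the induced possible-pair set, so its surface is piecewise
constant; the annealer crosses those plateaus via Metropolis moves at
positive temperature.

**Random.** One constant probability; its ML value is the connectance,
so fitting bypasses the annealer entirely.

AICc uses `n_obs = S_C·S_R` binary observations and is reported as
undefined (the model is excluded from ranking, with a warning) when
`n_obs ≤ k + 1`.

## Fitting

Simulated annealing with geometric cooling (`T ← 0.95·T` per sweep,
400 sweeps, 3 restarts by default; all configurable).  One sweep
proposes one move per parameter plus three families of structural moves
that the plain parameter walk explores poorly:

* *niche-edge moves* — perturb one edge of a consumer's interval
  (`c ∓ r/2`) holding the other edge fixed;
* *swap moves* — exchange the positions of two resources, or the whole
  niches `(c, r)` of two consumers;
* *window reflections* — reverse the axis inside a random interval,
  mirroring every position and center that falls in it.

Ordering moves matter because the likelihood over axis orderings is
multimodal: without them the annealer reliably converges to
wrong-ordering local optima whose likelihood trails the global basin by
5–20 nats on 15×15 networks.  Local proposals are Gaussian
(`sd = 0.05`, reflected at domain bounds) with a 10% chance of a uniform
redraw; `g` is proposed on the log scale and `p_max` on the logit scale.
The initial temperature is the standard deviation of the log-likelihood
over 50 random-parameter probes ("auto").

The first two restarts start from a spectral seriation: resources are
ordered by the leading principal component of their centered
consumption profiles, consumers placed at the mean position of their
diet with width proportional to the diet's span.  These informed starts
are quenched from a gentle fixed temperature (1.0) rather than the auto
temperature, which would randomize them.  Remaining restarts start
uniform.  After annealing, a zero-temperature polish (up to 400 sweeps,
alternating step sizes, stopping after 10 stagnant sweeps) refines the
best visited state; at zero temperature only strictly improving moves
are accepted, so plateau drift — which adds pure noise to the fitted
widths — is frozen out.

`AnnealConfig.fix_g` / `fix_p_max` optionally hold the two global
parameters fixed; the parameter-recovery experiment uses this to fit
with the kernel shape held at the generating values, estimating only the
species-level parameters, as recovery studies conventionally do.

The convergence flag records whether the final 10% of sweeps improved
the best log-likelihood by less than 1e−6.

## Metrics

* **Consumer NODF** sorts rows and columns by descending marginal totals
  (stable ties) and averages `100·|shared|/deg_narrow` over ordered
  column pairs whose degrees strictly differ.  Equal-degree pairs are
  *excluded* from the average rather than scored zero — fully
  overlapping equal diets arguably should not incur the maximum
  deduction — and zero-degree columns are likewise excluded; the
  original zero-scoring behavior is available behind a flag.  The score
  is undefined (None) when every pair is excluded.
* **Continuous overlap** applies the same scheme to the fitted niche
  intervals `[c − r/2, c + r/2]` (width exactly `r`, not clipped to the
  axis), sorted by decreasing width: pairs with strictly wider first
  interval score `100·|intersection|/r_narrow`; equal widths are
  excluded.  A quantile-based cutoff (where the kernel falls to 2.5% of
  its peak) is a documented alternative convention not used by default.
* **f_L** is the expected fraction of observed links realized by the
  model, `Σ_{A_ij=1} p_ij / L` — not a 0.5-threshold count (a threshold
  variant exists behind a flag).  The expectation form is what ties the
  measure's validity to `Σp ≈ L`; a warning fires when the model's
  expected link count deviates from the observed by more than 5%.
* **Connectance** comes in three flavors: empirical `L/(S_C·S_R)`,
  probability-sum `Σp/(S_C·S_R)`, and the mean over a simulated
  ensemble.
* **Ordering correlation** is Spearman (average ranks on ties) between
  consumer degree and fitted width; **center dispersion** is the sample
  standard deviation (n−1) of the fitted centers.

## Simulation and synthetic data

Realizations are independent Bernoulli draws per cell.  Ensemble member
`t` uses the sub-stream `SeedSequence(entropy=seed, spawn_key=(t,))`, so
ensembles are bit-reproducible and extendable.  The default ensemble
size is 100 networks.  Within ensembles, realizations whose NODF is
undefined are skipped for the NODF mean (and counted); every realization
contributes to connectance.

The synthetic generator draws resource positions uniformly and consumer
centers either uniformly ("mutualistic-like") or clumped around one or
more Gaussian peaks ("antagonistic-like"), with fixed or exponential
width laws — emulating the qualitative contrast between the two classes
of real networks (near-uniform vs strongly clumped niche centers) while
resource positions stay spread in both.  It does *not* emulate other
features of field data: sampling effort, phylogenetic correlation,
forbidden links, or the empirical joint distribution of size and
connectance.  Passing tests therefore show that the machinery recovers
the structures it models, not that real webs satisfy those structures.

Study-scale experiments use these desk-scale problem sizes: model
selection on 20 networks of 20×20 (exponential widths, mean 0.15,
`p_max = 0.95`), where niche structure is strong enough and the AICc
penalty small enough for the BPNM to dominate; the accuracy-vs-size
sweep over 5–50 species per side; recovery on 15×15.

## Parameter recovery and its limits

The canonical recovery instance (`well_spaced_niche_instance`) places
both species sets on lightly jittered even grids and gives consumers a
shuffled geometric ladder of widths from 0.1 to 1.0, so that adjacent
widths remain distinguishable at the resource spacing 1/S; the
realization uses `g = 2`, `p_max = 0.95`.  Recovery is scored after
resolving the axis's reflection symmetry (the likelihood is invariant
under `x → 1 − x`; the orientation maximizing correlation with truth is
taken).

A caution established while validating the fitter: at 15×15 the exact
maximum-likelihood point is *not* a reliable estimator of the width
ranking.  Refining fits to higher likelihood (e.g. with a quasi-Newton
polish) measurably *decreases* the Spearman correlation between true
and fitted widths — beyond a point, likelihood gains come from fitting
the realized noise, and the width ordering degrades.  Position recovery
(Pearson on `n`) is robust; width-rank recovery saturates around
0.8–0.85 median Spearman regardless of optimizer effort.  This is an
information limit of 225 binary observations, not an optimizer defect,
and it is why the recovery test's pass rate plateaus near 70% of
replicates under the joint 0.9/0.8 thresholds.

## A caveat on AICc and the niche model's effective complexity

AICc penalizes the BPNM for its `S_R + 2·S_C + 2` continuous
parameters, but the model's capacity also includes the *ordering* of
species along the latent axis — combinatorial structure worth on the
order of `log(S_R!)` nats that no parameter-count penalty sees.  With a
thorough optimizer this matters: on networks that are pure Bernoulli
noise, the fitted BPNM reliably compresses the noise by more than the
AICc penalty, so the niche model can out-rank the true (random)
generating model.  The model-selection re-enactment on noise networks
therefore fails its nominal expectation under the default (strong)
fitting configuration, and passes only when the optimizer underfits.
Practical reading: a BPNM-vs-random AICc margin needs to be large — or
validated against a null distribution of fits to degree-preserving
randomizations — before it is evidence of niche structure; small
margins are within the optimizer's noise-compression capacity.

## Study pipeline

`run_study` fits all requested models to each labeled network
(annealing seed = master seed + index), simulates the default
100-network ensemble from the BPNM fit, and assembles per-network
records; per-network failures are recorded, not raised.  The
overlap/connectance regressions are ordinary least squares of the
model-derived value on the empirical value (the direction is a
convention; residuals are paired with network size for the
departure-vs-size diagnostic).  The two-class comparison uses the
two-sample Kolmogorov–Smirnov statistic with the asymptotic p-value
(effective sample size `n₁n₂/(n₁+n₂)`), and Q-Q pairs match the sorted
smaller sample against interpolated quantiles of the larger.

## Known limitations

One-dimensional niche axis only; binary interactions only (no weights);
global `g` and `p_max` (no per-consumer shape); annealing is stochastic
— results are reproducible given a seed but two seeds can differ by a
few nats on large networks; the asymptotic KS p-value is approximate for
very small class counts.
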