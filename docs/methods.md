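# Methods

## Setting and sampling model

A phase III trial compares a new treatment with control in a full
population containing a pre-specified biomarker subpopulation S1 (fraction
λ) and its complement S2. The effects of interest are θ₁ (in S1), θ₂ (in
S2) and the overall effect θ₃ = λθ₁ + (1−λ)θ₂; the one-sided hypotheses
are H01: θ₁ ≤ 0 and H03: θ₃ ≤ 0 (θ₂ is not tested on its own). After a
fraction τ of the planned sample, an interim analysis either *enriches*
(recruits the rest of the sample from S1 only, abandoning the test of H03)
or continues in the full population.

With n patients randomised 1:1 and response SD σ, the full-trial estimate
of θ₃ carries information Ĩ = n/(4σ²), and every stage-wise effect
estimate is normal with a precision that is a product of Ĩ with the
relevant λ- and τ-fractions. All simulation therefore happens at the
summary-statistic level; no patient-level data are generated. By the same
construction (θ̂₃ the λ-weighted sum of independent subpopulation
estimates) the correlation between θ̂₁ and θ̂₃ at any stage is √λ.

Calibration: `calibrate_information(δ, power, α)` returns
((Φ⁻¹(power)+Φ⁻¹(1−α))/δ)², the information at which a single one-sided
level-α test of H03 has the stated power at θ₃ = δ. The reference
configuration used throughout the tests is λ = τ = 0.5, α = 0.025 and
Ĩ = 0.105 (90% power at δ = 10; n = 264 at σ = 25).

## Error control

Familywise error is controlled by closed testing: H01 is claimed only if
level-α tests reject both H01 and the intersection H0,13 (similarly H03).
The intersection is tested with Simes' p-value
S(p,q) = min{2 min(p,q), max(p,q)}, valid here because the two z-statistics
are positively associated. Stages are combined with the weighted
inverse-normal rule W(P⁽¹⁾,P⁽²⁾) = 1 − Φ(w₁Φ⁻¹(1−P⁽¹⁾) + w₂Φ⁻¹(1−P⁽²⁾)),
w₁²+w₂² = 1, which keeps the combined statistic standard normal under the
null *whatever* data-dependent enrichment rule is used — this is what
licenses optimising the rule freely. After enrichment no stage-2 estimate
of θ₃ exists; H03 is never rejected and the stage-2 intersection p-value
falls back to the stage-2 p-value for H01.

Default weights are w₁ = √τ, w₂ = √(1−τ). These are the unique weights
proportional to the square roots of the stage information fractions, and
they make the combined H01/H03 statistics equal, when no enrichment
occurs, to the z-statistics of the pooled full-data estimates (the
"pooling identity" checked in the tests). Boundary convention: p ≤ α
rejects.

Numerical guards: p-values are clamped to [1e−300, 1−1e−16] before Φ⁻¹,
and tail quantities use `ndtr(−z)` / `−ndtri(p)` to avoid cancellation.

## The interim decision

The gain function is G(θ, X) = λθ₁𝟙{only H01 rejected} + θ₃𝟙{H03
rejected}: a claim is rewarded in proportion to the population it covers
and the effect in that population. No sampling-cost term is included (the
total sample size is fixed and futility stopping is out of scope); custom
gains can be supplied through `GainSpec` but only the default is exercised
by the optimiser tests.

Given interim data x₁, the Bayes rule compares the conditional expected
gain of the two options under the posterior of θ:

* **Enrich.** The closed test after enrichment rejects H01 exactly when the
  stage-2 estimate reaches κ(x₁) = max(c₁, c₁₃)/√((1−τ)Ĩ) with
  c_j = (Φ⁻¹(1−α) − w₁z_j⁽¹⁾)/w₂ — both combined statistics are linear and
  increasing in the stage-2 estimate, so κ is exact (verified against
  bisection through the full closed test). The conditional gain is then the
  posterior average of λθ₁·Φ((θ₁−κ)√((1−τ)Ĩ)), i.e. stage 2 is integrated
  out analytically; only the posterior sampling contributes Monte Carlo
  noise. For a one-point prior this option is evaluated without any noise.
* **Continue.** One no-enrichment stage-2 dataset is simulated per
  posterior draw, pushed through the closed test with the fixed stage-1
  data, and the gain averaged. One replicate per draw is deliberate:
  variance comes mostly from θ and x₁, so extra posterior draws beat extra
  stage-2 replicates at equal cost.

One shared posterior sample (default M = 10⁵) serves both options — common
random numbers for the comparison. Ties, which have probability zero in
the exact problem, go to continuation (it preserves the ability to test
H03); a `z_tie` margin is available but defaults to strict comparison.

Priors: a one-point mass (the rule then adapts to sampling variability
only) or a bivariate normal, updated in closed form — the likelihood is
exactly bivariate normal with precision diag(λτĨ, (1−λ)τĨ), so the
conjugate normal-normal update is exact, not an approximation (checked
against a renormalised prior×likelihood grid). A zero variance on one
component is handled as a conditional update with that component known.

## Mapping the decision boundary

Operating characteristics need the decision at ~10⁵–10⁶ interim outcomes,
so the rule is precomputed over a rectangle A spanning the prior-predictive
mean ± 5.1 predictive SD per axis (missed mass < 1e−6 by a union bound).
A is split into four subcells; any cell whose four vertices carry the same
unambiguous decision inherits it, the rest are split again, down to a
minimum cell of 1/128 of the region side (dyadic halving, so the tiling is
exact in integer lattice coordinates). A vertex is *ambiguous* when its
two estimated gains differ by less than twice their combined Monte Carlo
SE; ambiguity forces subdivision exactly like disagreement, which is the
operational reading of "both decisions optimal at a vertex". Vertices are
shared and cached by lattice coordinates, and each vertex draws its RNG
stream from a seed keyed to those coordinates, so the map is reproducible
and independent of evaluation order. Leaf cells still mixed at the minimum
size take the majority of their four vertices, ties to continuation; an
optional refinement pass re-evaluates ambiguous vertices with a larger M.

Lookup is half-open (lower-left corner belongs to the cell) through a
raster at the finest resolution; points outside A clamp to the nearest
boundary cell, the "simple extrapolation" beyond the mapped region. The
exported JSON (region, resolution, cell list) reproduces the rule exactly;
a raster CSV at arbitrary resolution supports plotting the boundary.

In the reference configurations the build evaluates roughly 800–2000
vertices (out of 129² = 16 641 lattice points), 15–45 s at M = 10⁵ on one
core.

## Operating characteristics

`evaluate_adaptive` simulates, per replicate: θ from the prior, interim
estimates, boundary lookup, stage-2 estimates under the chosen option,
closed test, gain. `evaluate_ff` does the same for the single-stage
full-population design (closed test with a single-stage Simes p-value);
its estimates are formed as the λ-weighted sum of independent
subpopulation estimates, which reproduces the correct joint law by
construction. `evaluate_fs` is exact: P(reject | θ₁) = Φ(θ₁√Ĩ − z_α),
integrated over the θ₁ marginal by adaptive quadrature for normal priors.
Binomial/sample SEs are attached to every Monte Carlo figure.
`best_design_map` and `sweep` rebuild the optimal adaptive rule per grid
point / parameter value and tabulate comparisons, flagging winners within
2 combined SEs of the runner-up as statistical ties.

## Problem sizes and what the tests show

The acceptance-level tests and the reproduction script use M = 10⁵
posterior draws per vertex, the default 128-cell resolution, and 2–10 × 10⁵
evaluation replicates; at these sizes a full reference reproduction runs in
a few minutes on one core. Monte Carlo SEs at these sizes are ≲ 0.01 on
probabilities and ≲ 0.01 on expected gains; adaptive-design figures carry
an additional boundary-discretisation allowance of 0.05 because the mapped
rule is a step-function approximation to the exact boundary.

The synthetic-data layer *is* the model: estimates are drawn from the
exact normal summary-statistic laws, so these tests validate the decision
theory, the testing procedure and the numerics — they do not probe
non-normal endpoints, unequal randomisation, drift between stages, or
estimation of λ and σ, all of which real trials would raise and all of
which are out of scope here (large-sample normality is the standard bridge
for other endpoint types).

## Known limitations

* One subpopulation, one interim look; no futility stopping (would require
  a sampling-cost term in the gain).
* The boundary mapper assumes the enrich/continue regions are unions of
  modest numbers of regular pieces; a pathological gain function violating
  this would need a finer minimum cell.
* `best_design_map` labels can be statistically fragile where two designs'
  expected gains genuinely differ by less than Monte Carlo resolution;
  ties are flagged rather than hidden.
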