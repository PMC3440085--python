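# Methods

## Model

A substance's normalized response at concentration `C` (μM) is modeled
by the four-parameter Hill equation

    R(C) = R0 + (RMAX − R0) / (1 + (AC50/C)^SLOPE),

with responses in percent of the positive-control activity. `R0` is
the low-concentration asymptote, `RMAX` the high-concentration
asymptote, `AC50 > 0` the half-maximal concentration and `SLOPE > 0`
the shape parameter. Activation versus inhibition is carried entirely
by the sign of `RMAX − R0`, so `SLOPE` is always positive. The
equivalent logistic form `R0 + (RMAX − R0)·σ(SLOPE·(ln C − ln AC50))`
is used internally; it is algebraically identical and avoids overflow
for extreme slopes. Evaluation is undefined at `C ≤ 0`; all
log-concentrations are base-10 μM in user-facing output.

## Weighting scheme

The weighted procedures use neighbor-agreement weights: for included
point *i*, the disagreement `d_i` is the mean absolute response
difference to its available included neighbors (`i−1`, `i+1`), raw
weights are `1/(ε + d_i)` with `ε = 1` (one percent of positive
control), normalized so `Σ w_i = n`. The ε keeps weights finite on
perfectly flat stretches and makes flat data reduce exactly to equal
weights, in which case every weighted statistic in the package reduces
to its unweighted counterpart. The scheme gives an isolated spike the
smallest weight in its profile, which is the behavior the second
(weighted) fit needs in order to discount single-point "curves".

## Curve fitting

Both NLS and WNLS fits minimize `Σ w_i (R_i − R(C_i))²` (all `w_i = 1`
for NLS). Because the model is linear in `(R0, RMAX)` for fixed
`(AC50, SLOPE)`, candidate starts are generated by scanning 24
log-spaced `AC50` values spanning `[C_min/50, C_max·50]` crossed with
slopes `{0.25, 0.5, 1, 2, 4, 8, 16}` and solving the 2×2 weighted
linear subproblem in closed form at each node. The three best nodes
are polished by Levenberg–Marquardt with the analytic Jacobian;
parameter bounds (`AC50 ∈ [C_min/100, C_max·100]`, `SLOPE ∈ [0.01,
20]`, `R0`/`RMAX` within 1.5× the observed response span beyond the
data range) are enforced by a sigmoid change of variables, with a
bounded trust-region solver as fallback. Convergence tolerances are
1e-8 on cost and step. Ties between equally good optima are broken
toward the smaller slope. The whole procedure is deterministic given
the data, so NLS and WNLS with equal weights agree to optimizer
tolerance, and mirrored data produce exactly mirrored fits.

The start grid is dense enough that the popular single-start failure
mode of Hill fitting (converging to a boundary spike fit and missing
the global optimum) does not occur in testing; the unit suite checks
the fitted cost against an independent dense-grid + simplex minimizer.

## Outlier removal

Outlier detection is a two-step procedure combined with curve fitting:
(1) a preliminary Hill fit under a soft-L1 robust loss, so suspected
outliers do not drag the reference curve; (2) each scaled residual
`|r_i|/RSDR` is referred to a t distribution on `n − 4` degrees of
freedom, where RSDR is the robust residual SD (68.27th percentile of
`|r|`, inflated by `n/(n − 4)`), and points are flagged by a
Benjamini–Hochberg step-up at false-discovery rate Q = 0.01. At most
`⌈n/7⌉` points are removed, never leaving fewer than 4, and profiles
with fewer than 6 included points are left untouched. The RSDR is
floored at 1% of positive control so numerically clean profiles are
never flagged. An earlier design using a fixed 3.5×MAD residual cut
was rejected because it removed ~1.5% of points from well-behaved
Gaussian profiles and thereby roughly doubled the null rejection rate
of the downstream F-tests; the FDR form removes essentially nothing
(<0.1%) from clean noise while still catching gross artifacts.

## Tests and the decision tree

The overall F-test compares the 4-parameter Hill fit with the
1-parameter flat line sharing the same weights and points:
`F = [(SSE₀ − SSE₁)/3]/[SSE₁/(n − 4)]` on `F(3, n − 4)`. With `n = 4`
usable points, or a perfect zero-residual fit, the test is undefined
and treated as never significant — which is why four-point profiles
can only be called in stage 2.

The weighted one-sample t-test against a response threshold uses
`t = (m_w − θ)/(s_w/√n)` with `m_w = Σw_iR_i/Σw_i`,
`s_w² = Σw_i(R_i − m_w)²/(Σw_i − 1)` under the `Σw_i = n`
normalization, and `n − 1` degrees of freedom (an effective-sample-
size df was considered and not adopted; with near-equal weights the
two coincide, and `n − 1` keeps the equal-weight case exactly
Student's test). Zero-variance profiles give p = 0 when the mean is
beyond the threshold in the tested direction, else p = 1.

Stage order is fixed: robust concentration–response (both F-tests,
consistent direction, detection limit exceeded) → potent responder
(weighted t-test against the detection limit) → nonrobust response
(at least one F-test) → inactive. If activator and inhibitor branches
ever both qualify in stage 1 or 3, the branch with the larger excess
beyond its detection limit wins; in stage 2 the sign of the weighted
mean decides. These collisions cannot occur with a single fitted
direction and one-sided simulations; the rules only make the tree
total and sign-symmetric.

The stage-2 test uses the weighted mean of **all** included responses
against the detection limit. That reads the potent-responder
hypothesis literally ("responses exceed the limit on average") rather
than testing only the response at the lowest concentration, which a
one-point test could not do; a rejected test is what licenses the
toxicological reading that activity is present already at the lowest
tested concentration. MAX/MIN response conditions use the
outlier-masked responses, consistent with the fits they gate.

Detection limits default to ±25% of positive control — typical for
screens normalized to a baseline of 0 — or are estimated as mean ± 3
SD of negative-control responses.

For speed, `classify` skips the two Hill fits when they provably
cannot influence the call: when no response leaves the detection-limit
band (the stage-1/3 response conditions already fail, and the stage-2
t-test cannot reject for α < 0.5), and when only 4 points remain (the
F-test is undefined). `ClassifierConfig(always_fit=True)` forces the
fits for record completeness; the call itself is unchanged.

## Synthetic screens

The simulator emulates an unreplicated qHTS screen: 14 log-equally-
spaced concentrations from 4.90×10⁻⁴ to 76.63 μM (the production assay
range; it also brackets the simulated AC50 levels 10⁻³, 10⁻¹ and
10 μM so that potent, mid-range and partial-curve regimes all occur),
additive independent Gaussian error, and a mixture of 2,000 true
actives (|RMAX| ≥ 25%, R0 = 0, SLOPE = 1 by default) with 8,000 true
inactives (RMAX = R0 = 0). Error is either constant
(σ ∈ {5, 10, 25, 50, 100}% — 25% is the typical screen noise) or
heteroscedastic with σ(C) = 9.7355 + 0.1146·C, the linear noise–
concentration relationship observed in nuclear-receptor agonist
screens. Smaller sample sizes are produced by masking 1–10 of the 14
points uniformly at random, independently per substance. Per-profile
random streams are spawned from a single seed, so any profile can be
regenerated in isolation.

The generator does **not** emulate plate effects, spatial artifacts,
signal drift, replicate wells, non-Hill response shapes (biphasic,
gain–loss) or correlated errors. Passing operating-characteristic
tests therefore says how the procedure behaves under clean Hill +
Gaussian conditions, not under assay-specific systematic error.

## Evaluation

Type I error is the fraction of true nulls called `ACTIVE[±1]` or
`ACTIVE[±2]`; power is the same fraction over true actives;
`INCONCLUSIVE[±3]` counts as not active in both. The stage-1 share,
`ACTIVE[1]/(ACTIVE[1]+ACTIVE[2])·100`, is reported over the true
actives when any are present. ROC curves sweep the significance level
α over a log-spaced grid in [10⁻⁶, 0.999] — α is the only continuous
decision threshold in the algorithm; the detection-limit conditions
stay fixed, so the raw curve can terminate below (1, 1) and the (0,0)
and (1,1) anchors are appended only for the trapezoid-rule AUC. Each
dataset is classified once and the stored p-values are re-read at
every α. Five single-stage comparators are provided: the NLS and WNLS
F-tests with direction filtering, Huber-M robust regression of
response on log₁₀ concentration (tuning constant 1.345, normal
approximation for the slope test), and Student's and weighted t-tests
against ±25%.

## Problem sizes and defaults

Simulation-based tests in the suite run at reduced replicate counts
(typically 300–2,000 profiles per condition) with tolerances widened
by the corresponding binomial Monte-Carlo error;
`scripts/acceptance.py` runs the full 8,000-null / 2,000-active
conditions. α = 0.05 throughout, matching standard screening
practice.

## Known limitations

- The exact weighting formula and outlier rule used in the original
  characterization of this algorithm are not published in full; the
  concrete choices here (ε = 1 neighbor weights, FDR outlier cut) are
  principled reconstructions, and small-sample operating
  characteristics — especially the stage-2 power at n = 4, where the
  weighted t-test is the only active test — are sensitive to them.
- The F-reference distribution is exact only for linear models; for
  the Hill fit it is an approximation, and the aggressive global
  optimization makes the single-test null rejection rate slightly
  anticonservative (the three-stage combination still holds the
  empirical type I error near 0.02–0.03 at σ = 25%).
- Only the four-parameter monotone Hill family is fitted; biphasic or
  gain–loss profiles will be forced into it.
- Inference is per-substance; no multiplicity correction across a
  library is applied.
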