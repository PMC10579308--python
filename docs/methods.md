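# Methods

## Models

All responses are computed on a normalized scale: the system maximum
`E_MAX` defaults to 1, matching the usual practice of expressing functional
responses as a fraction of the system maximum after basal subtraction
(`normalize_responses` implements exactly that two-step transformation).
Concentrations are molar throughout; affinities and potencies are reported
as `pK_A = −log10(K_A)` and `pEC50 = −log10(EC50)`.

Closed-form response equations (`omafit.models`):

- hyperbolic operational model: `E = E_MAX·τ[A]/([A](τ+1)+K_A)`;
- Black & Leff slope-factor form: `E = [A]ⁿτⁿE_MAX/([A]ⁿτⁿ+([A]+K_A)ⁿ)`
  with asymptote `E_MAX·τⁿ/(1+τⁿ)` and
  `EC50 = K_A/((2+τⁿ)^{1/n}−1)`;
- Hill form: `E = [A]^{n_H}E'_MAX/([A]^{n_H}+EC50^{n_H})`, and its
  operational parameterization with `E'_MAX = E_MAX·τ/(τ+1)`,
  `EC50 = K_A/(τ+1)` — the slope leaves both untouched;
- two-slope (allosteric) form
  `E = [A]^{nm}τⁿE_MAX/([A]^{nm}τⁿ+([A]^m+K_A^m)ⁿ)` with binding slope
  `m`; `EC50 = K_A·(1/((2+τⁿ)^{1/n}−1))^{1/m}`.

Degenerate inputs are defined, not raised: `τ = 0` gives the zero response,
`[A] = 0` gives exactly 0 for any slope (the `0^n` limit), and an observed
maximum at the system maximum yields NaN efficacy with an explicit
`"tau_not_determinable"` flag — an unbounded `τ` is data, not an error.
Bell-shaped or biphasic responses are out of scope; none of these slope
forms can represent them.

The `EC50 > K_A` region of the Black & Leff model is bounded by
`τ* = (2ⁿ−2)^{1/n}`: empty for `n ≤ 1`, crossing `τ = 1` at
`n = log2 3 ≈ 1.585` and tending to 2 as `n → ∞`.  (For `τ = 0.5` the
region already opens at `n ≈ 1.27`, earlier than the `τ = 1` crossing —
a detail easy to misquote; tests anchor only the crossing and the
asymptote.)

## Mechanistic generators

Three explicit receptor–effector mechanisms produce non-hyperbolic curves
with known ground truth (`omafit.simulate`):

- **non-competitive auto-inhibition** (`σ = R_T/K_I`):
  `E = E_MAX · τ[A]/(K_A+[A](1+τ)) · σ[A]/(K_A+[A](1+σ))`; steep
  (fitted `n_H ≈ 1.2`), depressed maximum
  `E_MAX·τ/(1+τ)·σ/(1+σ)`, apparent efficacy `τ′ = στ/(σ+τ+1)` and a
  closed-form EC50.  The expression is exactly symmetric in `(τ, σ)`.
- **signalling feedback** (factor `δ`; `δ > 1` negative, flat curves;
  `δ < 1` positive, steep):
  `E = E_MAX·τ[A](τ[A]+[A]+K_A) /
  ([A]²(δτ+τ²+τ+1)+[A]K_A(δτ+τ+2)+K_A²)`;
  maximum `E_MAX(τ²+τ)/(δτ+τ²+τ+1)`, apparent efficacy
  `τ′ = (τ²+τ)/(δτ+1)`; `δ = 1` reproduces the plain hyperbola exactly.
  Its EC50 has no convenient closed form and is obtained by root
  bracketing.  A by-product of our verification: the EC50/K_A ratio rises
  with `δ` for `τ > 2`, falls for `τ < 2`, and at `τ = 2` the EC50 is
  exactly `K_A/3` for every `δ`.
- **receptor–effector depletion** (`R_T ≈ G_T`): occupancy
  `[RA] = R_T[A]/([A]+K_A)` feeds the exact quadratic root
  `[RAG] = (K_E+[RA]+G_T−√(K_E²+2K_E([RA]+G_T)+([RA]−G_T)²))/2`,
  evaluated in the cancellation-free product-over-sum form; the response is
  `[RAG]/G_T` (the plotted 0–1 scale with `G_T` as the effector total).
  Curves are steep and asymmetric, more so for larger `τ = R_T/K_E`.  A
  closed form of `[RAG]` directly in `[A]` exists only approximately, so
  the two-step evaluation is used.  Kinetic and stochastic simulation are
  out of scope.

## Synthetic agonist panel

`synth_agonist_panel` emulates a functional screen of 4 agonists × 5
pathways with Hill-based operational curves: efficacies τ from 0.1 to 30,
affinities pK_A 5–8, heterogeneous Hill slopes within 0.5–1.5 (varying by
agonist *and* pathway, as seen in real G-protein activation panels),
homoscedastic Gaussian replicate noise (SD 0.02 of the system maximum,
5 replicates — typical of normalized GTPγS-type data with symmetric error
bars), on 15 half-log concentrations from 1e-10 to 1e-3 M.  One seeded
generator covers a panel; the ground truth travels in curve metadata.

Pathway P3 carries a deliberately discordant pair: a steep weak agonist
(n_H 1.5, observed maximum 0.15) against a flat agonist with a three-fold
higher maximum (n_H 0.7, maximum 0.45).  Fitted noiselessly, the
Hill-derived efficacies preserve the true ordering while the Black & Leff
efficacies invert it — the structural failure mode of exponentiated
efficacy.  Both maxima must lie below `E_MAX/2` for a clean inversion:
`τⁿ` pins the asymptote, so a Black & Leff `τ` cannot cross 1 unless the
observed maximum does.  The regression test pins the deterministic limit;
under replicate noise the Black & Leff estimate wanders its ridge (see
below) and can land on either side.

What the generator does *not* emulate: heteroscedastic or proportional
error, between-day E_MAX drift, compound solubility cut-offs, and
mechanistic (rather than Hill-shaped) slope heterogeneity.  Passing tests
therefore demonstrate properties of the estimators, not assay realism.

## Fitting

Unweighted least squares on normalized responses (no weighting scheme is
assumed for the emulated data), via bounded `scipy.optimize.least_squares`
in a positivity-preserving parameterization: `log10 τ` (and `log10 σ`,
`log10 δ`), `pK_A`/`pEC50`, slope linear.  Bounds: slope ∈ [0.2, 5],
`log10 τ` ∈ [−4, 7], `pK_A` ∈ [2, 12] — generous margins around every
scenario in the recovery experiments and the panel.  Conventions:

- **Hill fit**: estimates `(E'_MAX, pEC50, n_H)` with `E'_MAX` capped at
  the system maximum ("confined ≤ 1"); when a system `E_MAX` is supplied
  the operational pair `(τ, pK_A)` is derived by inverting the hyperbolic
  relations.  A maximum at the cap flags `τ` as not determinable.
- **Black & Leff fit**: `E_MAX` fixed (default 1), estimates
  `(τ, pK_A, n)` plus the exponentiated efficacy `τⁿ`.
- **Mechanistic fits** (auto-inhibition, feedback): `E_MAX` fixed,
  estimates `(τ, σ or δ, pK_A)`.  The auto-inhibition τ/σ exchange
  symmetry is detected by evaluating the swapped parameter vector; results
  are reported in canonical order `τ ≤ σ` with `symmetry_flag` set.  The
  symmetry makes the pair individually unidentifiable from a single curve
  — only `τ′` is well determined.

Multi-start is deterministic: a grid over `log10 τ ∈ {−1, 0, 1}` × slope
`∈ {0.7, 1, 1.5}` plus a heuristic start from a Hill prefit; lowest
residual sum of squares wins, ties broken toward the smaller slope.
Standard errors come from the pseudo-inverse curvature at the optimum
(delta method back to the reporting scale); when near-optimal restarts
disagree by more than 10% the result carries an `"se_unreliable"` flag.
Non-convergence is flagged on the `FitResult`, never raised, so panel
pipelines keep running.  The numeric EC50 oracle brackets the half-maximum
on the log10 axis with Brent's method (relative precision ≲ 1e-9) and
doubles as the feedback EC50 and the independent check of every closed
form.

Back-calculation of `K_A` from a fitted EC50 exploits that each mechanism's
EC50 is proportional to `K_A` at fixed shape parameters: closed-form ratio
for auto-inhibition, unit-`K_A` numeric ratio for feedback.  The full
recovery pipeline (Hill fit → `τ′` → mechanism inversion → `K_A`) returns
the generating `pK_A` to two decimals on all auto-inhibition and feedback
scenarios.

### The Black & Leff ridge

On auto-inhibition curves the Black & Leff objective is nearly degenerate:
`τⁿ` and the EC50 are pinned by the data while `(n, τ, pK_A)` trade off
along a ridge whose residual varies by orders of magnitude less than the
response scale.  For the weakest scenario (`τ = 0.2`, `σ = 1`) the ridge
runs from `(n ≈ 1.2, τ ≈ 0.14)` to the true optimum
`(n ≈ 1.88, τ ≈ 0.28)` with residual sums of squares 6e-5 → 6e-8 on a
61-point noiseless grid.  Any estimate along it reproduces the curve
visually, so an under-converged optimizer can report `τ` anywhere between
a 30% underestimate and a 40% overestimate of the modelled 0.2.  `omafit`
always reports the ridge minimum (multi-start, lowest rss) and exposes the
degeneracy through `multistart_spread` and the `se_unreliable` flag.  This
is the strongest form of the package's central caution: on such data the
exponentiated-efficacy fit does not carry reliable information about `τ`
itself — only `τⁿ ≈ τ′` is stable.

## Recovery experiments and bias metrics

`recovery_experiment` runs the full table for one mechanism: noiseless
curves on the default grid (61 log-spaced points, 1e-10–1e-2 M — dense
enough that fits are grid-insensitive, wide enough that every scenario
reaches 99% of its plateau), both fits, closed-form `τ′`, and the
mechanism-aware back-calculated `pK_A`.  Tables export at 3 significant
figures.  For depletion the reference `τ′` equals the modelled `τ` (the
depletion mechanism leaves the apparent efficacy unchanged); Hill-derived
efficacies recover it within 10% for `τ ≤ 100`, and the `τ = 1000` full
agonist is reported as not determinable.

`rank_and_bias` computes `log10(τ/K_A)` and the intrinsic-activity ratio
`log10(E'_MAX/EC50)` per curve, Δ against a reference agonist within each
pathway, and ΔΔ between pathway pairs with the documented sign convention
Δ(pathway₁) − Δ(pathway₂).  With `E_MAX = 1` the two Δ metrics agree
exactly (the `τ+1` factors cancel in differences).  Black & Leff
comparisons across curves whose fitted slopes differ by more than 0.1 are
flagged: with unequal exponents, `log(τ/K_A)` differences are not
interpretable as bias.  Hypothesis testing across replicate fits (ANOVA
and post-hoc contrasts) is intentionally out of scope.

## Problem sizes

The shipped experiments are desk-scale by construction: recovery tables
are 5 curves × 61 points per mechanism, the panel 20 curve groups × 15
concentrations × 5 replicates, and the noise-bias check 200 seeded
refits of one curve group.  Everything is regenerated programmatically;
no data files ship with the package.

## Known limitations

- Global multi-curve fitting with a shared `K_A` across receptor-density
  series is not implemented; single-curve fits require the system `E_MAX`
  to be fixed externally.
- Standard errors are local-curvature estimates; along the Black & Leff
  ridge they understate the true uncertainty, which is why the spread flag
  exists.
- The feedback EC50 is numeric only; its closed form is unwieldy and adds
  nothing at the achieved precision (closed forms and the root bracketer
  agree to 1e-6 relative everywhere they are both defined).
- The depletion mechanism is fitted only through the Hill/Black & Leff
  equations; fitting the two-step depletion model itself is not exposed.
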