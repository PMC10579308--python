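# omafit

Simulation, constrained fitting and diagnostics for the **operational model
of agonism (OMA)** — the standard framework pharmacologists use to turn
concentration–response curves into agonist efficacies and, downstream, into
signalling-bias estimates.

## The problem

The OMA describes the functional response to an agonist A as

```
E = E_MAX · τ·[A] / ([A]·(τ + 1) + K_A)
```

with the system maximum `E_MAX`, the agonist equilibrium dissociation
constant `K_A` (M) and the operational efficacy `τ` (the transducer ratio
`R_T/K_E`).  The observed maximum and potency follow as
`E'_MAX = E_MAX·τ/(τ+1)` and `EC50 = K_A/(τ+1)`.

Real curves are often steeper or flatter than this hyperbola, and two slope
factors compete to describe them:

- **Black & Leff slope factor `n`** — both `[A]` *and* `τ` are
  exponentiated:
  `E = [A]ⁿτⁿE_MAX / ([A]ⁿτⁿ + ([A]+K_A)ⁿ)`, so
  `E'_MAX = E_MAX·τⁿ/(1+τⁿ)` and `EC50 = K_A/((2+τⁿ)^(1/n) − 1)`.
  The slope factor now distorts the efficacy–maximum and potency–affinity
  relations: for `τ < (2ⁿ−2)^(1/n)` it even makes `EC50 > K_A`, which no
  plain mass-action receptor system can do.
- **Hill coefficient `n_H`** — steepness changes while midpoint and
  asymptote stay put:
  `E = [A]^{n_H}·E'_MAX / ([A]^{n_H} + EC50^{n_H})` with `E'_MAX` and
  `EC50` pinned to their operational values.

`omafit` implements both, plus three mechanistic generators that produce
genuinely non-hyperbolic curves with *known* ground truth (non-competitive
auto-inhibition with factor `σ = R_T/K_I`; signalling feedback with factor
`δ`; receptor–effector depletion with `R_T ≈ G_T`), and a constrained
least-squares layer that quantifies what each fitting equation does to the
parameters.  The headline result: when curve slopes vary between agonists,
exponentiating `τ` (Black & Leff) can scramble or even invert the efficacy
ranking, while the Hill-based fit recovers the apparent efficacy
`τ′ = E'_MAX/(E_MAX − E'_MAX)` faithfully.

## Worked example

Simulate a negative-feedback system (`τ = 5`, `δ = 5`, `pK_A = 6`) and fit
both equations:

```python
from omafit import (MechanismParams, apparent_tau, fit_blackleff, fit_hill,
                    make_log_grid, simulate_feedback)

grid = make_log_grid(-10, -2, 61)
curve = simulate_feedback(grid, MechanismParams("feedback", k_a=1e-6, tau=5.0, delta=5.0))
print(apparent_tau("feedback", 5.0, delta=5.0))   # 1.1538...
print(fit_hill(curve, e_max_system=1.0).estimates)
# {'e_max_observed': 0.539, 'p_ec50': 6.556, 'n_h': 0.784,
#  'tau': 1.171, 'p_k_a': 6.220}
bl = fit_blackleff(curve)
print(bl.estimates, bl.tau_exponentiated)
# {'tau': 1.243, 'p_k_a': 5.862, 'n': 0.659}  1.154
```

Reading these numbers: the feedback mechanism makes the curve flat
(`n_H ≈ 0.78`) and caps the observed maximum at 0.539, so the *apparent*
efficacy is `τ′ ≈ 1.15`, not the modelled 5.  The Hill fit recovers `τ′`
(1.17) on the nose; the Black & Leff `τ` (1.24) is four-fold below the
modelled efficacy and only its exponentiated form `τⁿ = 1.154` tracks
`τ′`.  With the mechanism known, `invert_apparent_tau` and `backcalc_ka`
recover the modelled `τ = 5` and `pK_A = 6` from the Hill estimates.

The same pipelines are scriptable from the shell:

```bash
omafit recover-tables --mechanism feedback --delta 5 --out tables/
omafit simulate --out panel/ --seed 1
omafit fit --input panel/curves.csv --model hill --model blackleff --emax 1 --out fits/
omafit region --n-min 1 --n-max 4 --out region/
omafit bias --input panel/curves.csv --reference A2 --emax 1 --out bias/
```

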