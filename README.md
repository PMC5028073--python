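# gemdyn

Inter-trial fluctuation dynamics near a goal equivalent manifold (GEM), for a
redundant virtual shuffleboard task.

## The problem

In a shuffleboard trial a puck is released at position *x* with speed *v* and
slides to rest under Coulomb friction μ. In dimensionless units (lengths over
*R* = 20 cm, speeds over √(2gR), target at *L̃* = *L*/*R* = 10) the goal-level
error is

    e = f(x, v) = v²/μ + x − 10,

and the set of perfect releases, f(x, v) = 0, is a parabola in the (x, v)
plane — the **goal equivalent manifold**. The task is redundant: infinitely
many release states hit the target, and only deviations *normal* to the GEM
produce error, amplified by the passive sensitivity *s* = ‖(1, 2v*/μ)‖, the
singular value of the goal-function Jacobian at the operating point.

Skilled performers fluctuate from trial to trial near the GEM. Modeling the
fluctuations u<sub>k</sub> = x<sub>k</sub> − x* as a noisy linear update

    u[k+1] = B u[k] + ν[k],

the eigenstructure of B tells you how errors are regulated: a **weakly
stable** eigendirection (λ_w somewhat below 1) nearly tangent to the GEM,
where deviations are allowed to persist, and a **strongly stable** direction
(λ_s ≈ 0) transverse to it, where goal-relevant deviations are corrected
within a trial. Persistence measures (lag-1 autocorrelation, which for the
diagonalized dynamics equals the eigenvalue; DFA exponents α) probe the same
structure independently. The quantities combine into the **total body-goal
sensitivity**

    s_TOT = β s / √(1 − λ_s²),     β = sin θ_s,

predicting the scaling σ_e/σ_ns = a·s_TOT + b with a ≈ 1, b ≈ 0 across
friction conditions. Because the analysis rests on eigenvalues rather than
variances, its conclusions survive arbitrary invertible coordinate changes —
including a PCA-whitening transform that erases the variance signature of the
GEM entirely.

The package provides, as library modules plus a thin `gemdyn` CLI:

- `task` — goal function, GEM geometry, passive sensitivity, friction sets;
- `simulate` — a generator of blocked trial series with known ground truth;
- `estimation` — fluctuation extraction with block trimming, OLS fit of B,
  labeled eigenanalysis, residual noise scales;
- `persistence` — lag-1 autocorrelation and linearly detrended DFA;
- `resampling` — vectorized pair bootstrap (10000 iterates) for all
  dynamical quantities, including the eigenbasis bootstrap for DFA;
- `scaling` — per-condition performance points, the s_TOT fit and its
  bootstrap, H1–H4 hypothesis verdicts;
- `invariance` — coordinate transforms, whitening, invariance checks;
- `io` / `pipeline` / `cli` — CSV + YAML interchange, the end-to-end
  pipeline, and the JSON report.

## Worked example

```sh
gemdyn simulate --seed 3 --out sim/          # 8 friction conditions, 500 trials each
gemdyn analyze sim/*.csv --seed 1 --out report.json
gemdyn report report.json
```

prints (pooled across the 8 conditions, 10000 bootstrap iterates):

```
conditions: C1-t3.00s, C2-t3.29s, C3-t3.57s, C4-t3.86s, C5-t4.14s, C6-t4.43s, C7-t4.71s, C8-t5.00s
  lambda_w       +0.767  95% CI [+0.689, +0.844]
  lambda_s       -0.021  95% CI [-0.172, +0.101]
  theta_w_deg    +2.837  95% CI [-3.586, +8.882]
  theta_s_deg   +79.027  95% CI [+70.366, +87.604]
  R_w1           +0.767  95% CI [+0.689, +0.844]
  R_s1           -0.022  95% CI [-0.172, +0.101]
  alpha_w        +0.978  95% CI [+0.838, +1.081]
  alpha_s        +0.528  95% CI [+0.427, +0.598]
  scaling: a=1.009 b=-0.286 R^2=0.9265
  H1: PASS
  H2: PASS
  H3: PASS
  H4: PASS
```

Reading: the weak eigenvalue sits near 0.76 with its eigenvector about 1° off
the GEM tangent (persistent drift along the manifold), the strong eigenvalue
is indistinguishable from 0 at ~80° (one-trial correction of goal-relevant
error), the lag-1 autocorrelations reproduce the eigenvalues, the DFA
exponents separate cleanly (α_w ≈ 1 vs α_s ≈ 0.5), and the error/noise ratio
scales with s_TOT with unit slope. All four hypothesis checks (H1 weak
control along the GEM, H2 strong control transverse, H3 persistence
anisotropy, H4 the scaling law) pass.

Experimental data in the same CSV schema (`block, trial, x, v, e`
dimensionless or `x_cm, v_cm_s, e_cm` with a YAML task config) runs through
the identical `analyze` path.

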