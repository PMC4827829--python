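# dmreg — circular–circular regression with row-deletion outlier detection

`dmreg` fits the Downs–Mardia regression of one circular variable on
another and screens the fitted model for influential observations with a
row-deletion statistic calibrated by Monte-Carlo simulation.  It is aimed
at analysts of paired angular data — times of day mapped to the circle
(circadian peak times measured in two periods), wind or current directions,
seasonal phases — who need both a parametric link between two angles and a
principled way to flag the single observation that distorts it most.

## The model and the statistic

Angles live on `[0, 2π)`.  The Downs–Mardia model links a dependent angle
*v* to an independent angle *u* through

```
tan½(v − β) = ω · tan½(u − α),        −1 ≤ ω ≤ 1,
```

a one-to-one map of the circle for ω ≠ 0, with angular locations α, β and
slope ω.  The conditional mean direction is
`μ(u) = β + 2 atan(ω tan½(u − α))`, and the angular errors are assumed
von Mises VM(0, κ).  The log-likelihood for n pairs is

```
ℓ(α, β, ω; κ) = −n log I₀(κ) + κ Σⱼ cos(vⱼ − μ(uⱼ)) + const,
```

so for fixed (α, β, ω) the precision `ρ̂ = (1/n) Σ cos(vⱼ − μ(uⱼ))` is the
mean residual cosine, and the MLE of κ is the Bessel-ratio inverse
`κ̂ = A₁⁻¹(ρ̂)` with `A₁ = I₁/I₀`.  `dmreg.fit` maximizes ρ̂ by an
exhaustive lattice search over (α, β, ω) followed by a bounded
derivative-free simplex refinement.

Goodness of fit is summarized by the mean circular error of the residuals
`dⱼ = π − |π − |vⱼ − v̂ⱼ||`:

```
MCEs = (1/n) Σⱼ sin(dⱼ/2)  ∈ [0, 1].
```

Deleting observation *j* and recomputing gives MCEs₍₋ⱼ₎; the detection
statistic is the largest absolute change

```
DMCEs = maxⱼ |MCEs − MCEs₍₋ⱼ₎|,
```

and an observation is flagged when DMCEs exceeds an upper percentile of
the statistic simulated on clean data at the fitted concentration (the
cut-off point).  See `docs/methods.md` for the two supported residual-sign
conventions and how the calibration tables were validated.

## Worked example

Generate the bundled synthetic "circadian-style" dataset — ten paired
blood-pressure peak times with the response of subject 8 moved to its
anti-mode — then fit and screen it:

```
$ dmreg simulate --preset circadian --seed 0 --out circ.csv
$ dmreg detect circ.csv --cutoff 0.07 --signed --no-refit --out report.json
dmreg: seed=0 refit=False signed=True
dmreg: observation 8 flagged (DMCEs=0.0959 > cutoff=0.0700)
```

The report shows one per-observation deletion effect an order of magnitude
above the rest — 0.0959 for subject 8 against 0.0006–0.0357 for the
others — so subject 8 is flagged as an influential observation at the 0.07
cut-off.  Removing it and refitting moves the estimates from
(α̂, β̂, ω̂) = (48.6°, 20.3°, 0.356) to (44.5°, 17.6°, 0.437): the flagged
point was pulling the slope down.  Without a known cut-off, `dmreg detect`
simulates one at the fitted κ̂ (`--level 0.05 --reps 2000`), mirroring the
fit → calibrate → detect workflow.

The same machinery is scriptable from Python:

```python
import dmreg

scheme = dmreg.SimScheme(n=30, error_kappa=10, reps=2000, seed=1)
table = dmreg.cutoff_table(scheme, levels=(0.10, 0.05, 0.01))
print(table.table)          # simulated cut-off points for n=30, kappa=10
```

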