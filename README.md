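# neutralsar

Spatially explicit neutral biodiversity theory: analytic species–area
relationships, distance decay of community similarity, and an exact
individual-based simulator of the underlying stochastic process.

## The problem

The species–area relationship (SAR) — how the number of distinct species
grows with the area sampled — is among the most robust patterns in ecology,
and the power-law exponent of its intermediate phase is a standard currency
in conservation and macroecology. `neutralsar` implements a *bottom-up*
prediction of the SAR: no assumption about species abundances or spatial
clustering, only mechanistic per-individual rules shared by all species
(ecological neutrality):

* every individual dies at rate `d` and reproduces at rate `b`, with the
  offspring dispersed a random distance (diffusion scale `σ`);
* `d` slightly exceeds `b` (`α = d/b − 1 > 0`), so each lineage eventually
  dies out;
* extinction is balanced by point speciation — new species arise as single
  founding individuals at rate `θ_s·b` per unit area.

The package is aimed at theoretical ecologists and macroecologists who need
(1) fast, numerically safe evaluation of the equilibrium predictions,
(2) a trustworthy simulator of the same process for validation or for study
regimes the analytics do not cover, and (3) an estimation pipeline from
point-pattern data `(x, y, species)` to fitted parameters and an extrapolated
SAR.

## The theory in brief

For a circular sample of radius `R` the expected richness follows from the
equilibrium window generating function; with `κ = √α/σ`:

    S(R) = (θ_s π R² / α) · (1 + αG) / (1 − G) · ln( (1 + Gα) / (G(1 + α)) ),
    G(R) = (R / (2σ²κ)) · K₀(κR)/K₁(κR) + R²/(8σ²),

where `K₀, K₁` are modified Bessel functions (evaluated in exponentially
scaled form, so the curve is finite over ten orders of magnitude of area).
The curve is **triphasic**: near-linear for `A < σ²` (the sampling phase),
approximately a power law `S ∝ A^z` for `σ² < A < σ²/α`, and exactly linear,
`S = θ_s A ln((1+α)/α)`, beyond — where `σ` drops out entirely. The exponent

    z(α) = d log S / d log A   at   log R = log σ − ¼ log α

depends on `α` alone; for the tropical-forest value `α ≈ 1e-7` it equals
**0.21**, in the canonical empirical range. Two companion predictions close
the loop with data: the density of individuals `⟨J⟩ = θ_s/α`, and the
probability that two individuals separated by `r` are conspecific,

    F(r) = K₀(√α·r/σ) · α / (2π σ² θ_s),

which decays exponentially beyond the correlation length `σ/√α` — the reason
the SAR turns linear at `A ≈ σ²/α`. Because `F(r)` has the same `K₀` shape as
the classic spatial-neutral distance-decay result, a measured `F(r)` plus the
observed density identify `(α, σ, θ_s)` and let the fitted SAR extrapolate
richness far beyond the censused area.

## Worked example

Fifty lines of science in ten: simulate a community at a desk-scale regime,
then recover its parameters from the pattern alone.

```python
import neutralsar as ns

params = ns.make_params(alpha=0.05, sigma=1.0, theta_s=0.25)
print(ns.expected_density(params))        # 5.0 individuals / unit area
pr = ns.phase_report(params)
print(pr.A_small, pr.A_large, round(pr.z, 4))   # 1.0  20.0  0.6202
print(round(ns.power_law_exponent(1e-7), 4))    # 0.2137  -> z = 0.21

comm = ns.equilibrate(params, None, L=60.0, seed=1)
print(comm.n, comm.n_species)             # 17409 individuals, 2689 species
res, sar, phase = ns.predict_sar_from_data(points=comm, measure_seed=0)
print(res.summary())
```

The fit report printed by the last line:

```
Distance-decay fit (neutral community)
==============================================
points used                                 12
observed density                       4.83583
alpha (d/b - 1)                      0.0491232
sigma (dispersal)                      1.04285
theta_s (diversity/area)              0.237552
amplitude 1/(2 pi s^2 rho)           0.0302625
objective (wtd SSR, logF)             0.0174573
----------------------------------------------
power-law exponent z                    0.6192
phase boundary sigma^2                 1.08754
phase boundary s^2/alpha                22.139
```

Reading it: from one snapshot of 17 409 points the pipeline recovers
`α ≈ 0.049` (truth 0.05), `σ ≈ 1.04` (truth 1.0) and `θ_s ≈ 0.238`
(truth 0.25), and reports the implied SAR phase structure; `sar` holds the
extrapolated species–area curve over 40 radii.

The same operations are available from the shell:

```bash
neutralsar exponent --alpha 1e-7                       # prints 0.21
neutralsar predict --alpha 0.01 --sigma 1 --theta-s 1 \
    --radii-log 0.1:1000:50 --out sar.tsv
neutralsar simulate --alpha 0.2 --theta-s 0.5 --side 40 \
    --equilibrate --seed 7 --out pts.csv
neutralsar measure beta --in pts.csv --bins 1.25:10:9 --seed 3 --out beta.tsv
neutralsar fit --in pts.csv --out fit.json
neutralsar validate --alpha 0.2 --seed 0               # sim-vs-theory report
```

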