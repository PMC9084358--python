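# ch4iso

Isotopic mass-balance attribution of changes in atmospheric methane:
a two-hemisphere ¹²CH₄/¹³CH₄ box model with inverse OH estimation, a
factorial emission-scenario ensemble with Monte Carlo source-signature
uncertainty, an idealized-wetland inversion, and most-likely-scenario
selection with period-based source attribution.

## The problem

Atmospheric CH₄ resumed growing after its 2000–2006 plateau while its
carbon-isotope ratio (δ¹³C-CH₄) declined, and competing explanations —
more fossil emissions, more agriculture and waste, more wetlands, less OH —
can all fit the concentration record alone. The isotope record
discriminates between them because sources carry distinct δ¹³C signatures
(biogenic ≈ −60‰, fossil ≈ −44‰, pyrogenic ≈ −24‰) and the OH sink
fractionates (ε < 0 enriches the residual atmosphere). `ch4iso` is a
reusable implementation of that attribution machinery for scientists who
want to test emission hypotheses against the paired CH₄/δ¹³C records.

## The model

Each hemisphere h ∈ {N, S} and isotopologue x ∈ {12, 13} obeys the explicit
annual difference equation

    m_x^h(t+1) = m_x^h(t) + S_x^h(t) − k_x(t)·m_x^h(t)
                 − [m_x^h(t) − m_x^h'(t)] / (2 τ_ex)

with τ_ex = 1 yr, k₁₂ = k_OH + k_minor, k₁₃ = α·k₁₂ and
α = 1 + ε/1000 (ε the sink-weighted fractionation, ‰). δ values follow
δ¹³C = (¹³m/¹²m / R_std − 1)·10³ with R_std = 1.12372% (VPDB). Mixing ratios
convert at 2.767 Tg ppb⁻¹ (configurable).

Run **inverse**, the model solves, per year and exactly:

* `invert_oh` — k_OH(t) from the linear global CH₄ balance, so every
  scenario reproduces the observed CH₄ record to rounding;
* `fit_epsilon` — ε by bracketed root finding so the simulated δ¹³C matches
  the observed mean over the onset window (first three years);
* `invert_wetland` — a per-year 2×2 linear solve for (wetland flux, k_OH)
  reproducing *both* observed tracers ("idealized wetlands").

Run **forward**, scenarios built from the factorial catalogue
(4 IFF × 3 AGW × 2 WET × 2 BB × 2 GEO = 96) with 1000 Monte Carlo draws of
the emission-weighted source signatures are scored against observed δ¹³C
(RMSE, Taylor statistics, MSD); the "most likely" subset is the first
percentile of lowest MSD (960 of 96 000), over which flux changes relative
to the 2000–2006 plateau are attributed to IFF/AGW/WET.

A synthetic-data generator supplies every input — gridded sector fluxes,
signature maps with cell-level 1-σ, and pseudo-observations produced by the
forward model from a known truth — so the full pipeline is testable with no
downloads.

## Worked example

```python
from ch4iso import (IsotopeBudgetModel, TruthConfig, generate_world,
                    make_scenario_catalogue, build_sector_signature_draws,
                    run_ensemble, EnsembleConfig)

world = generate_world(TruthConfig(seed=0).noise_free())
draws = build_sector_signature_draws(world.signature_specs(), 1, seed=0,
                                     sigma_scale=0.0)
result = IsotopeBudgetModel(world.observations, world.truth_scenario(),
                            draws, 0).fit()
print(result.summary())

catalogue = make_scenario_catalogue(world)          # 4 x 3 x 2 x 2 x 2 = 96
draws = build_sector_signature_draws(world.signature_specs(), 50, seed=0)
ensemble = run_ensemble(catalogue, draws, world.observations,
                        EnsembleConfig(n_draws=50, seed=0))
chosen = ensemble.select(1.0)
print(f"{ensemble.n_runs} runs, {len(chosen)} in the first percentile; "
      f"best run: {chosen.iloc[0]['run_id']} "
      f"(RMSE {chosen.iloc[0]['rmse']:.4f} permil)")
```

prints

```
===================== Isotope budget fit =====================
scenario:        IFF0-AGW0-WET0-BB0-GEO0   draw: 0
years:           1993-2017
epsilon:           -6.900 permil
mean lifetime:       9.29 yr
mean source d13C:  -54.96 permil
feasible:        True
===================== delta13C agreement =====================
RMSE:      0.0000 permil    MSD:     0.000000 permil^2
r:         1.0000           cRMSE:     0.0000 permil
SD sim:    0.1169 permil    SD obs:    0.1169 permil
==============================================================
4800 runs, 48 in the first percentile; best run: IFF0-AGW0-WET0-BB0-GEO0/d0000 (RMSE 0.0008 permil)
```

The fit on the noise-free truth recovers the prescribed fractionation
(ε = −6.9‰) and lifetime exactly (RMSE 0), and the truth scenario tops the
96-scenario × 50-draw ensemble. With observation noise and signature
uncertainty switched on, runs spread over RMSE ≈ 0.05–0.5‰ and selection
starts to favour scenarios whose trend biases compensate each other — the
behaviour the method is designed to expose.

The same pipeline is scriptable from the shell:

```sh
ch4iso synth --out world --seed 1
ch4iso ensemble --world world --out scores.csv --draws 1000 --seed 1
ch4iso select --scores scores.csv --out selected.csv --percentile 1
ch4iso wetland-invert --world world --out wetland.csv
ch4iso attribute --world world --scores scores.csv --out report.json
```

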