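# Methods

## Model and assumptions

The troposphere is two perfectly mixed boxes (northern / southern
hemisphere) exchanging with a constant timescale τ_ex = 1 yr, each
carrying separate ¹²CH₄ and ¹³CH₄ burdens in Tg. The update is the
explicit annual difference equation itself — not a continuous ODE solve —
because the budget is posed on annual data and every inverse solver
exploits the fact that one step is *linear* in the removal rate and in any
single source flux. (The explicit exchange step is stable for
τ_ex ≥ Δt/2; with the annual step and τ_ex = 1 yr this always holds.)

Removal is first order: ¹²CH₄ at rate k_OH(t) + k_minor, ¹³CH₄ at
α·(k_OH + k_minor) with α = 1 + ε/1000. All rate variability is carried by
OH; k_minor defaults to 0 because the soil sink enters as a flux (below)
and Cl/stratospheric losses are held constant with their fractionation
folded into the total ε. The model tracks full isotopologue masses — δ is
computed only at reporting time from ¹³m/¹²m against R_std = 1.12372%
(VPDB) — and the global δ is always derived from mass-summed
isotopologues, never from averaged hemispheric deltas. In the governing
equations the ¹²C removal rate applies to ¹²CH₄ in both hemispheres; a
hemisphere-asymmetric isotope rate would be unphysical for a globally
mixed sink.

Sources per hemisphere are category sums (IFF, AGW, WET, BB, GEO, OTH)
minus a constant soil uptake. Each category flux is split exactly into
isotopologues, ¹³S/¹²S = R_std(1 + δ/1000) with ¹²S + ¹³S = S, rather
than the common approximation ¹³S = R·S, which carries a ~1% bias.

Two numerical choices deserve emphasis:

* **Soil uptake is a flux at a fixed δ.** Uptake is subtracted as its own
  isotopologue flux with δ = −47.3‰ (configurable), the contemporary
  atmospheric value, since soil microbes consume ambient air; the soil
  kinetic fractionation is part of ε. This keeps the net forcing exactly
  linear in the source categories, so removing a category (the idealized
  wetland mode) removes exactly its contribution. Scaling all sources by
  (S − S_soil)/S instead would couple the categories through the soil term
  and leak percent-level errors into the wetland inversion.
* **δ aggregation happens at the isotopologue level.** Whenever a single
  "effective" δ must represent a flux mixture (e.g. the global wetland δ
  feeding the 2×2 inversion), it is computed by splitting, summing and
  re-deriving δ — not by flux-weighted averaging of δ values. The wetland
  system's determinant is small (the wetland δ sits only a few ‰ from the
  removal-adjusted atmospheric δ), so the second-order error of an
  arithmetic mean would be amplified into percent-level flux errors.

Emission-weighted *category* signatures, by contrast, are computed as
flux-weighted δ means over map cells and member sectors — that is the
quantity the signature datasets define — and only then split into
isotopologue fluxes. Forward and inverse modes share this construction,
so they are mutually consistent by definition.

## Inverse solvers

**OH inversion.** Given start-of-year state, sources and α, the global
balance M(t+1) = M + S − κ(M₁₂ + αM₁₃) is solved for κ per year, so the
simulated CH₄ burden equals the observation at every year end exactly
(machine rounding; the test suite enforces < 10⁻⁶ ppb on a forward
re-run). Years implying κ ≤ k_minor are flagged infeasible; an ensemble
run with any such year is scored as failed and excluded from selection,
never aborted.

**ε optimization.** ε is fitted so the simulated δ¹³C matches the observed
mean over the onset window (default: the first three observation years,
damping single-year noise), with the OH inversion nested inside each
evaluation (ε outer, OH inner — the two are not fitted jointly). The
residual is monotone in ε (a more negative ε leaves a heavier atmosphere),
so bracketed root finding on ε ∈ [−12, −1] ‰ (scipy `brentq` on the scalar
path, 60-step bisection on the vectorized path; both verified to agree to
10⁻⁸ ‰) always converges when a root exists; a bracket without sign change
marks the run failed and reports the residual curve.

Because ε is constrained *only* at the onset, δ-observation noise in those
years propagates into ε with considerable leverage (±0.04‰ noise → roughly
±0.5‰ in ε) and the fitted trajectory inherits a corresponding drift.
This is a property of the method, not of the implementation: it is why
ensemble runs spread over RMSE ≈ 0.05–0.5‰ once noise is on, and why
selection can favour scenarios whose trend biases compensate. The
noise-free recovery tests isolate the solver itself (ε recovered to
< 0.01‰, in practice ~10⁻¹²).

**Idealized wetland inversion.** With every non-wetland source prescribed,
the ¹²CH₄ and ¹³CH₄ balances are linear in the two unknowns (wetland flux
W, removal rate κ); each year is a 2×2 solve, marched forward. The
determinant vanishes when the wetland δ equals the removal-adjusted
atmospheric δ (the two balances become collinear); such years are flagged
and bridged with the CH₄-only balance (W = 0) so a single degenerate year
cannot abort an ensemble member. Negative W is flagged and retained. The
hemispheric split of W follows the scenario's wetland candidate and
affects only the hemispheric distribution, never the global match. On
noise-free synthetic truths the recovered wetland series and trend are
exact to ~10⁻¹² relative; the acceptance gate is 5% on the trend across 20
seeds.

## Evaluation and attribution

Runs are scored on annual global δ¹³C over the full observation window:
RMSE, MSD (= RMSE²), Pearson r, simulated/observed SD and centered RMSE
(population SDs, so the Taylor identity holds to 10⁻¹⁰). MSD is unweighted
— the observational 0.04‰ 1-σ can weight the misfit but is off by
default. Selection keeps the floor(p/100·n) lowest-MSD feasible runs
(p = 1%; 960 of 96 000), ties broken by stable run-id order so results are
independent of execution order.

Attribution measures period-mean flux changes against the 2000–2006
plateau for the named regimes (1993–1999, 2007–2012, 2013–2017, and the
2007–2017 composite = renewed + accelerated growth). Headline shares
divide each category's Δ by the summed Δ of IFF + AGW + WET only; BB, GEO
and OTH deltas are reported separately. Per-run shares are kept raw — with
mixed-sign deltas they can be negative or exceed 100% — and the ensemble
spread is the 1-σ across the per-run raw shares of the selected subset
(runs with ~zero summed Δ are excluded and counted). ¹³CH₄-mass shares per
category-year use the exact isotopologue split and sum to 100% by
construction. Wetland diagnostics use a 7-year centered moving average
(edge-truncated) anchored at 2001, and an OLS trend with a two-sided
t-test at 95% (constant series: slope 0, p = 1 by convention; the test's
type-I error is verified at ≈5% over 1000 white-noise replicates).

## Monte Carlo signature sampling

Spatially resolved categories carry a flux-weight map and a δ¹³C map with
per-cell 1-σ; draws perturb cells independently (no spatial correlation
model), clip to [−120, 10] ‰, and reduce to one emission-weighted δ per
hemisphere (cells assigned by center latitude, ≥ 0 → N; cells are not
split at the equator). Scalar sectors draw one Gaussian value per
realization. Draw i of sector s comes from the dedicated substream
`default_rng([seed, crc32(s), i])`, making every draw reproducible from
(seed, index) and the ensemble independent of evaluation order. Cell-wise
independence is the implemented reading of "Gaussian map perturbation";
a fully correlated variant (`mode="offset"`, one shared deviate per map
and draw) is available for sensitivity work but is not the default.

The ensemble engine vectorizes all draws of a scenario through the same
marches as the scalar Model API (cross-checked in the tests), which keeps
the full 96 × 1000 ensemble near 15 s on one CPU.

## Synthetic worlds

The generator emulates the study's data situation: ~550 Tg yr⁻¹ gross
source in 1993 split over ten sectors with configurable trends, steps and
IAV; a +7.3 Tg step in tropical wetlands at 2007; signature means per the
compiled tables (coal −45.8‰, oil & gas −43.8‰, livestock −65.4‰,
biomass burning −23.9‰) with one wetland map carrying an enriched
tropical band (−56.7‰) and a depleted boreal band (−67.8‰), so the
flux-weighted wetland δ (−59.7‰) shifts toward the tropical value as the
tropical share grows; ε = −6.9‰; an OH rate series with ±0.5% sinusoidal
IAV around a steady-state base (lifetime ≈ 9.3 yr); observation noise of
0.5 ppb and 0.04‰ 1-σ. Grids are a coarse 18 × 36 mesh with schematic
band placement (fossil sources mid-latitude north, wetlands
tropical + boreal) — enough to create hemispheric contrast, with no claim
to inventory realism. The scenario catalogue surrounds the truth with
candidates emulating systematic inventory disagreements (steeper/flatter
trends, magnitude biases, a step-free wetland product, flat biomass
burning, geological source at 52 vs 15 Tg yr⁻¹), enumerating to
4 × 3 × 2 × 2 × 2 = 96.

What passing tests show — and what they do not: the recovery and selection
tests demonstrate that the solvers are exact and the pipeline identifies
the generating scenario when observations are noise-free and signatures
unperturbed. They do not demonstrate that real inventories are correctly
ranked: real data add spatially correlated signature errors, inventory
biases outside the catalogue, and interhemispheric transport variability
that a two-box model cannot represent. The "truth attains minimum MSD"
statement is therefore checked in the noise-free limit, where "the truth
run" is well defined; with noise on, the refit ε absorbs constant δ
offsets and near-ties between compensating scenarios are expected.

## Parameter defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| τ_ex | 1 | yr | standard interhemispheric exchange time; global results are insensitive to it |
| R_std | 1.12372% | – | VPDB ¹³C/¹²C |
| Tg per ppb | 2.767 | Tg ppb⁻¹ | whole-atmosphere factor (≈1.725×10²⁰ mol air); surfaced in config |
| ε bracket | [−12, −1] | ‰ | spans published sink-weighted fractionations with margin |
| onset window | 3 | yr | damps single-year observation noise in the ε fit |
| n_draws | 1000 | – | Monte Carlo signature realizations per scenario |
| percentile | 1 | % | most-likely cut (floor of n) |
| δ-obs 1-σ | 0.04 | ‰ | network/scale-conversion uncertainty of the global record |
| soil uptake | 30 (2:1 N:S) | Tg yr⁻¹ | climatological placeholder, overridable |
| soil δ | −47.3 | ‰ | uptake consumes ambient air; keeps forcing linear in categories |
| clip bounds | [−120, 10] | ‰ | guards unphysical Gaussian tails |

## Known limitations

Annual resolution only; no seasonal cycle, no 3-D transport, no explicit
OH chemistry or Cl/stratospheric sink terms; hemispheric observations are
not assimilated (global δ only, to avoid leaning on interhemispheric
transport the model cannot resolve); signature perturbations are spatially
uncorrelated; the ε/OH split is nested, not joint, so any real covariance
between sink fractionation and OH variability is not explored; and the
scenario catalogue is factorial over independent category candidates,
which cannot represent correlated inventory errors across categories.
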