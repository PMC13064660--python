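# Methods

`isoring` traces oxygen and carbon isotope signals from the leaf to dated
tree-ring subsections for a boreal Scots pine stand, entirely on synthetic
forcing. This note documents the model, the numerical choices, what the
synthetic generator does and does not emulate, and the design decisions made
where the problem was genuinely open.

## Model chain

**Leaf water (nonsteady state).** The leaf-water isotope ratio `R_lw` relaxes
toward the Craig–Gordon steady state

    R_lw,ss = α⁺ [ α_k (w_i − w_a)/w_i · R_sw + (w_a/w_i) · R_v ]

at rate `E·w_i / (W α⁺ α_k (w_i − w_a))`, where `W` is leaf water content
(5.6 mol m⁻², all-sided), `E` transpiration, `w_i`/`w_a` leaf-internal and
ambient vapor mole fractions, `R_sw`/`R_v` source-water and vapor ratios.
`α⁺(T)` is the liquid–vapor equilibrium fractionation (Majoube 1971 closed
form, ε⁺(20 °C) ≈ 9.8‰; swappable), and `α_k` the kinetic fractionation
`1 + (g_b ε_ks + g_s ε_kb)/(g_b + g_s)` with ε_ks = 28‰ (stomata) and
ε_kb = 19‰ (boundary layer) — the resistance-weighted mean written in
conductances. Péclet and two-pool corrections are omitted; in cool boreal
canopies they alter leaf-water δ¹⁸O only marginally.

**Leaf sugar.** The leaf sugar pool (constant `C_ls` = 1.96×10⁵ µmol C m⁻²)
relaxes toward the new-assimilate ratio `α_wc R_lw` at rate `(A_n + r_d)/C_ls`;
discharge into the phloem equals `A_n`. The biochemical fractionation
ε_wc(T) is 27‰ for T ≥ 20 °C rising linearly to 31‰ at 5 °C (clamped below,
CSV-overridable): the published curve behind it is only constrained by its
warm plateau and cold-end incline, so the lookup is deliberately replaceable.
The carbon pathway uses a linear discrimination stand-in
Δ = a + (b − a)·c_i/c_a (a = 4.4‰, b = 27‰, configuration not calibration) in
place of a full photosynthesis model; only the input contract
(A_n, r_d, g_s, g_b, E, w_i, w_a, c_i/c_a) matters downstream.

**Phloem pool.** A single well-mixed store:

    dC_ps/dt = A_n − F_wood − k C_ps
    d(C_ps R_ps)/dt = A_n R_ls − F_wood (1−e) R_ps − k C_ps (1−x) R_ps

with turnover `k = 30 yr⁻¹`, wood respiration `F_wood = 0.25 r_d` tracked per
timestep, and `e = x = 0` so isotopologue mass is conserved. Starch storage
and remobilization are deliberately absent.

**Cellulose and wood.** Each subsection window accumulates
`∫α_wc R_sw C_ps dt`, `∫R_ps C_ps dt` and `∫C_ps dt`; cellulose mixes the
exchange and phloem terms with `p_ex = 0.36`:

    R_cel = p_ex ⟨α_wc R_sw⟩ + (1 − p_ex) ⟨R_ps⟩

and the carbon value is the same expression at `p_ex = 0`. Constant offsets
(−4.4‰ O, −1.1‰ C) convert cellulose to resin-extracted wood. When `p_ex` is
a function of a covariate (DOY, A_n-weighted RH), it is evaluated once per
subsection at the window covariate — the mixing applies `p_ex` outside the
integrals, and a per-window evaluation matches the granularity at which
apparent p_ex can be inferred at all.

**Dating.** Xylogenesis curves map dates to relative ring position; a
subsection's window runs from the date formation reaches its relative start
(floored to a day) to the date maturation reaches `min(rel_end, 0.97)`
(ceiled). The 0.97 cap exists because full-ring maturation dates trail into
winter. Inverse lookup interpolates linearly and takes the first date
reaching the threshold on flat segments. Trees are averaged by densifying
each series to a 0.001 relative-position grid (values inside subsections,
linear interpolation between them, edge fill) and binning into
`round(mean subsection count)` equal-width bins; grid points are assigned to
bins by position (nearest-bin for values straddling an edge).

**Source water.** A single well-mixed bucket (capacity 150 mm): rain and
degree-day snowmelt enter at the precipitation composition; ET and overflow
drainage leave at the store's composition without fractionation. This damps
and lags precipitation δ¹⁸O by a few weeks. No soil-evaporation enrichment,
no depth-resolved uptake; external precipitation-isotope series can be
bias-corrected by a constant site offset before entering the bucket.

## Numerics

* Both leaf-level relaxation equations use the exact exponential per-step
  update: the leaf-water rate corresponds to turnover times of tens of
  minutes at high transpiration, faster than the 30-min step, so explicit
  stepping would be unstable. Nighttime and `w_i ≤ w_a` steps freeze `R_lw`
  (the zero-exchange limit; transpiration into saturated air exchanges no
  vapor).
* The phloem carbon pool has an exact linear-ODE step; the isotopologue mass
  uses the exponential update with the step-average pool size, and the
  recorded per-step outflow is the exact integral of that discrete model, so
  the cumulative budget closes to ~1e-14 relative (tested at 1e-9).
* Pools are simulated per calendar year over day-of-year 91–305 with a
  30-day spin-up (leaf water starts at its first valid steady state, leaf
  sugar at the new-assimilate ratio, `C_ps` at the fixed point of the
  spin-up-mean fluxes, floored at 3×10⁵ µmol C m⁻²). The floor stands in for
  overwintered reserves: without starch, post-season respiration would
  drain the pool below zero, and a depleted pool raises an error rather than
  going negative silently. All dated windows end by ~doy 300 under the 0.97
  cap.
* Fractionation temperature dependences are evaluated with air temperature
  clipped to their −5…45 °C domain.
* Window aggregation weights: `max(A_n, 0)` (night fixes no carbon, so
  negative exchange is clamped rather than admitted as a negative weight),
  a fixed 9–15 h window, or clear-sky cosine-of-zenith. Season membership
  (EGS/MGS/LGS) uses the window center date, boundary days to the earlier
  season.

## Synthetic forcing

The generator emulates the *structure* of half-hourly boreal flux-site
drivers, not any particular site's statistics: sinusoidal seasonal and
diurnal cycles with AR(1) daily residuals (ρ = 0.75; the real drivers'
day-to-day autocorrelation is not published, so the AR parameters are
configuration); precipitation as a seeded event process (~750 mm yr⁻¹);
RH anticorrelated with temperature within days; PAR from clear-sky geometry
times cloudiness; a supply-limited soil bucket; precipitation δ¹⁸O as a
summer-maximum sinusoid with AR(1) noise; vapor δ¹⁸O at liquid–vapor
equilibrium with precipitation; gas exchange from a saturating light
response with VPD, soil-moisture and cold-ramp modifiers (dark A_n = −r_d
exactly); double-Gompertz growth curves (maturation lagging formation by
~18 days); 2–15 Dirichlet-width subsections per tree.

Observation noise: ≤0.2‰ analytical (O; 0.25‰ for laser-ablation C) per
subsection plus between-tree deviations of 0.7–0.8‰ drawn **per tree and
year** — observed between-tree correlations are far too weak for persistent
whole-series offsets. Two presets ("southern_boreal", "northern_boreal")
differ in latitude, temperature (4.1 vs 0.1 °C mean), growing-season span
and precipitation δ¹⁸O level (2.3‰ apart).

What passing tests therefore show: the machinery (pools, dating, averaging,
inversion, grids) is correct and internally consistent, and the emergent
behaviors (travel-time lag, RH dominance, damped source-water signal) arise
from the stated physics. They do not show that any site's measured
correlations or MAEs are reproduced — the synthetic world has, e.g.,
seasonally-coupled rather than site-specifically-correlated RH and δ¹⁸O_sw,
and a constant true p_ex, so inverted apparent p_ex is flat by construction.

## Experiments

* **Travel-time lag.** Ring values integrate the phloem pool, whose isotope
  ratio relaxes at rate `A_n/C_ps`; with `C_ps ≈ (Ā − F̄)/k` the implied
  residence time is `(1 − F̄/Ā)/k ≈ 11 days`, nearly independent of the
  assimilation level. The dating-sensitivity grid (±20 days on formation and
  maturation dates) accordingly peaks when windows are shifted ~10 days
  early. The lag is read on the grid diagonal (uniform shift of both dates)
  at the most negative r — the RH signal is anticorrelated a priori — and
  reported as the median over seed replicates, because a single season's ten
  subsections leave the 2-D |r| argmax noisy. A planted dating misalignment
  (+10 days) is recovered by the same grid within one cell.
* **Apparent p_ex.** Inverting the mixing equation per subsection from
  (noisy) observed wood values (+4.4‰ to cellulose scale) against the modeled
  integral terms; ±0.5‰ observational uncertainty propagates to a band;
  values outside [0, 1] are flagged, never clipped. Pooled fits: OLS line in
  DOY and a two-parameter exponential decay in RH (the nonlinear form is not
  uniquely determined by the problem; the exponential is the default and
  swappable).
* **Recovery.** p_ex is re-estimated by MAE minimization on a 0.001 grid
  (the objective is piecewise linear in p_ex, so grid search is exact at
  that resolution) over three seasons × five trees. Noiseless recovery is
  exact to <0.01; under the configured noise ~95% of seeds land within
  ±0.05, consistent with the 0.7‰/√(5·3·subsections) propagated scatter
  against the ~13‰ separation of the mixing endmembers.
* **Source-water scenarios.** δ¹⁸O_sw variability is scaled around its mean
  (`s = 1` reuses the original array, so the baseline is bit-identical);
  correlations of modeled ring δ¹⁸O with RH and δ¹⁸O_sw trade off
  monotonically in `s` once enough windows are pooled; `s = 0` leaves the
  ring–source-water correlation undefined (flagged) and the RH pathway
  carrying the whole signal.

Problem sizes: analyses run on one synthetic decade (two sites, five trees,
~110 mean-series subsections) or on one-to-three seasons per seed for the
replicated experiments; a full decade simulates in roughly a second.

## Known limitations

Constant leaf temperature = air temperature; no canopy radiation or energy
balance; no starch pool (hence the spring reserve floor); the bucket ignores
soil-profile and meltwater isotope structure (a real weakness at northern
sites); the carbon pathway's discrimination stand-in carries no mesophyll or
post-photosynthetic effects, so absolute δ¹³C levels are offset; two-pool
wood composition (75/25 cellulose/lignin ± 5 pp) is used only as an
uncertainty half-range with a constant cellulose–lignin offset inferred from
the wood–cellulose offset.
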