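# isoring

Isotope-enabled leaf-to-tree-ring modeling of δ¹⁸O and δ¹³C for boreal
Scots pine, with xylogenesis-based dating of intra-annual ring subsections
and the signal analyses built on top — all runnable on synthetic forcing,
with no external data.

Tree-ring δ¹⁸O mixes two environmental signals: leaf-water evaporative
enrichment (driven by relative humidity) and source-water δ¹⁸O (driven by
precipitation isotopes and soil storage). Disentangling them at
intra-annual resolution requires (i) a process model from leaf to ring and
(ii) knowing *when* each ring subsection formed. This package implements
both for researchers in isotope dendroclimatology and tree ecophysiology.

## The model

Leaf water follows the nonsteady-state Craig–Gordon formulation,

    dR_lw/dt = E·w_i / (W α⁺ α_k (w_i − w_a)) · (R_lw,ss − R_lw),
    R_lw,ss  = α⁺ [ α_k (w_i − w_a)/w_i · R_sw + (w_a/w_i) R_v ],

feeding a leaf sugar pool (ratio relaxing toward α_wc·R_lw at rate
(A_n + r_d)/C_ls) and a well-mixed phloem pool,

    dC_ps/dt = A_n − F_wood − k C_ps,

whose isotope budget conserves isotopologue mass. Cellulose of a ring
subsection integrates the phloem signal over its formation–maturation
window (dated by growth curves, maturation capped at relative position
0.97) and exchanges a fraction p_ex of its oxygen with source water:

    R_cel = p_ex ⟨α_wc R_sw⟩ + (1 − p_ex) ⟨R_ps⟩,

with ⟨·⟩ the C_ps-weighted window means; δ¹³C is the same integral at
p_ex = 0. Defaults: W = 5.6 mol m⁻², C_ls = 1.96×10⁵ µmol C m⁻²,
k = 30 yr⁻¹, p_ex = 0.36, ε_ks = 28‰, ε_kb = 19‰, wood–cellulose offsets
−4.4‰ (O) and −1.1‰ (C). See `docs/methods.md` for the full account.

## Worked example

```python
from isoring.chronology import window_for_subsection
from isoring.params import IsotopeParams
from isoring.synthetic import SOUTHERN_BOREAL, build_dataset
from isoring.transport import run_forward

ds = build_dataset(SOUTHERN_BOREAL, (2015, 2015), seed=1)
curves = ds.growth_curves[2015]
windows = [window_for_subsection(curves, i / 10, (i + 1) / 10) for i in range(10)]
fwd = run_forward(ds.drivers, windows, IsotopeParams())
print(fwd.table[["start_doy", "end_doy", "d18o_wood_permil",
                 "rh_an_weighted_pct"]].round(2).to_string(index=False))
```

prints the ten dated subsections of the 2015 ring with their modeled
resin-extracted-wood δ¹⁸O and the A_n-weighted RH of each window:

```
 start_doy  end_doy  d18o_wood_permil  rh_an_weighted_pct
       156      184             21.57               64.13
       166      190             21.85               67.39
       172      195             21.66               70.62
       177      200             21.34               73.15
       182      205             21.03               71.29
       187      210             21.00               68.73
       192      216             21.28               65.66
       198      224             21.86               63.11
       207      238             22.80               62.82
       220      259             22.80               70.13
```

The anticorrelation is visible directly: the mid-season humid spell
(RH 73%) produces the lightest wood (21.0‰), the dry late-July window the
heaviest. Ring values lag their drivers by ~10 days — the travel time of
assimilates through the leaf and phloem pools.

## Analysis chain

Numbered drivers under `analysis/` reproduce the full study flow on a
synthetic decade for two site presets (each accepts `--seed`):

1. `01_simulate.py` — drivers, isotope forcings, growth curves, layouts
2. `02_forward.py` — five noisy trees → mean ring series → dated windows →
   forward model
3. `03_correlations.py` — intra-annual/interannual/seasonal correlations
4. `04_dating_sensitivity.py` — correlation grids over ±20-day date shifts
5. `05_apparent_pex.py` — apparent-p_ex inversion and covariate fits
6. `06_sw_scenarios.py` — source-water variability scenario sweep
7. `07_parameter_recovery.py` — p_ex recovery under observation noise

Outputs land under `results/<site>/` as plain CSV with a JSON manifest
(config hash, seed, version) for reproducibility.

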