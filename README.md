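# semdust

Presence-absence analysis of coal dust in passively collected settled-dust
samples by single-particle SEM-EDX, as a tested, fully synthetic-data-driven
pipeline:

1. **`semdust.synthetic_dust`** — generates settled-dust particle tables
   with ground truth (position, size L, thickness, class, intrinsic
   composition over the ten analyzed elements C, O, Na, Mg, Al, Si, P, S,
   Ca, Fe). The default mixture emulates dust near an open-air coal
   terminal: a terminal-coal class (measured C ≈ 83 ± σ3.9 At.%,
   O ≈ 14 At.%), inorganic minerals (low C / high O), carbonaceous fibrous
   and spherical confounders, and metallic debris. Confounder abundances
   and all size distributions are illustrative defaults (the calibration
   data constrain only the 0.5–100 µm observed range) and fully
   configurable.
2. **`semdust.edx_measurement`** — substrate-aware EDX forward model. Thin
   particles on conductive carbon tape (C 94 / O 6 At.%) do not contain the
   full beam interaction volume, so measured composition drifts toward the
   substrate: measured = close(f·intrinsic + (1−f)·substrate + noise) with
   f = min(1, thickness / penetration depth). The reference-flake thickness
   model is calibrated so on-tape mean measured carbon is ≈93 At.% below
   the 5 µm size limit and ≈87 At.% above it, returning to ≈82 At.% on a
   carbon-free planchette.
3. **`semdust.mc_electron`** — single-scattering electron-trajectory Monte
   Carlo (screened-Rutherford elastic scattering, Bethe/Joy–Luo continuous
   slowing-down) giving the penetration-depth rationale for the
   conservative L > 5 µm size cutoff; the Kanaya–Okayama closed-form range
   serves as an independent cross-check.
4. **`semdust.classify`** — the three-criterion coal call: L > 5 µm
   (strict), measured C ≥ 75 At.% and O ≤ 20 At.% (inclusive), and
   mineral-like morphology; every failed criterion is recorded.
5. **`semdust.survey`** — the manual stop-rule survey protocol: sets of
   nine saved 0.066 mm² fields of view, anticlockwise particle selection
   from the FOV center in groups of ten, stopping at ≥5 coal particles or
   ≥100 total particles (whichever first, evaluated at position boundaries
   by default), with non-overlapping position-set renewal until the region
   is exhausted.
6. **`semdust.metrics`** — loading and fraction summaries (particles/mm²,
   coal particles/mm², coal %), with report rounding fixed to reproduce
   the published summary table digit-for-digit, plus a deliberately
   non-inferential two-site comparison.
7. **`semdust.io` / `semdust.cli`** — CSV particle tables, YAML run
   configuration, reports, run manifests, and the `semdust` command.

## CLI

```sh
# synthesize a sample near-terminal dust table (with ground truth)
semdust simulate --seed 1 --out particles.csv

# run the stop-rule survey over it (measure + classify + summarize)
semdust survey --particles particles.csv --seed 1 --out survey

# summary-table row from published-style counts
semdust report --positions 8 --analyzed 82 --coal 7

# electron penetration depth in carbon
semdust mc-depth --energy-kev 15 --density 1.3 --n 5000 --seed 1

# classify an already-measured particle table (no ground truth needed)
semdust classify --particles measured.csv --out classified.csv

# everything end-to-end, with a reproducibility manifest
semdust pipeline --seed 1 --out-dir run1
```

Configuration is YAML with `protocol`, `beam`, and `sample` sections; see
`semdust.io.load_config` for the schema. Every stage draws from its own
stream spawned from the single master seed, so identical (config, seed)
pairs give byte-identical outputs.

## Particle-table schema

UTF-8 CSV, `.` decimal separator, one header row:

```
id,x_mm,y_mm,L_um,morphology,C_atpct,O_atpct,Na_atpct,Mg_atpct,Al_atpct,Si_atpct,P_atpct,S_atpct,Ca_atpct,Fe_atpct[,particle_class,thickness_um][,decision,reject_reasons]
```

`morphology` ∈ {mineral_like, fibrous, spherical, other}. Compositions are
closed to 100 At.% over exactly the ten analyzed elements; any other
`*_atpct` column is a hard error. `particle_class` and `thickness_um` are
synthetic ground truth only and are never required by downstream code.
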