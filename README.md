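# thermoflim

Phasor-based FLIM thermometry and molecular-dynamics post-processing for
studying heat released by protein aggregation in cells — in particular the
question of whether intracellular amyloid-β (Aβ42) aggregation raises
cell-averaged temperature, and which molecular factors (ions, peptide
packing, protein–water hydrogen bonding) slow heat dissipation from a
peptide into its surroundings.

The package is for microscopists analysing TCSPC FLIM data from
fluorescent polymeric thermometers (FPTs) or FRET sensors, and for
computational biophysicists post-processing thermal-relaxation MD output.
Every input the pipelines consume can be generated synthetically with
known ground truth, so the whole analysis chain is testable without a
microscope or an MD engine.

## What it computes

**Phasor FLIM thermometry.** A per-pixel photon arrival-time histogram
c(t) with excitation period P is mapped to first-harmonic phasor
coordinates

    g = Σ c cos(ωt) / Σ c,   s = Σ c sin(ωt) / Σ c,   ω = 2π/P.

Mono-exponential decays lie on the universal semicircle
(g − ½)² + s² = ¼; the phase and modulation lifetimes

    τ_φ = s / (gω),   τ_M = (1/ω) √(1/(g² + s²) − 1)

coincide only for mono-exponential decays (τ_φ < τ_M for mixtures — the
signature of the FPTs' bi-exponential emission). Instrumental bias is
removed by referencing against a standard of known lifetime (e.g.
Rhodamine B). Cell-averaged phasors are photon-weighted (equivalently the
phasor of the pooled decay), and τ_M — the more temperature-sensitive
parameter — is converted to °C through a monotone polynomial calibration
fitted to measured (T, τ_M) pairs. Groups of cells (control, aggregating,
drug- or uncoupler-treated) are compared with one-way ANOVA and pairwise
Welch t tests under Holm–Šidák step-down correction
(p_adj(i) = max_{j≤i} [1 − (1 − p_(j))^(m−j+1)]). A time-domain
bi-exponential fitter handles FRET donor (CFP-like) decays, reporting the
amplitude-weighted mean lifetime τ_m = (a₁τ₁ + a₂τ₂)/(a₁ + a₂).

**MD thermal-relaxation analysis.** Given chain-temperature time series
from a simulation in which a heated protein (e.g. 400 K) relaxes toward a
300 K solvent bath, the exponential model
T(t) = T_bath + (T₀ − T_bath) e^(−t/τ_relax) is fitted per chain; a linear
model of τ_relax vs chain length interpolates to 42 amino acids
(full-length Aβ42). Trajectory operators: subsystem kinetic temperature
2·KE/(k_B·N_dof), minimum-image radial distribution functions g(r) of
ions around charged termini, geometric protein–water hydrogen-bond counts
(D–A ≤ 3.5 Å, D–H···A ≥ 150° by default), mass-weighted radius of
gyration, hydration-shell selection, and water diffusivity D = slope/6
from all-time-origin mean squared displacements.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Render a two-cell scene at known temperatures and recover them through
the full phasor → reference-calibration → thermometry path:

```python
from thermoflim.synthetic import SceneConfig, TruthCalibration, simulate_flim_scene
from thermoflim.experiments import recover_scene_temperatures

calib = TruthCalibration()  # tau_M = 0.7 + 0.05*T (ns) over 25-45 degC
scene = simulate_flim_scene(
    SceneConfig(shape=(16, 16), cell_temperatures=[30.0, 40.0],
                photons_per_pixel=5000.0, seed=1),
    calib=calib,
)
print(recover_scene_temperatures(scene, calib).to_string(index=False))
```

```
 cell_id  T_C  tau_M_ns  tau_M_rec_ns   T_rec_C status
       1 30.0       2.2      2.201601 30.032018     ok
       2 40.0       2.7      2.677808 39.556163     ok
```

Each cell is a 4×4-pixel region at 5000 expected photons per pixel
(8×10⁴ per cell). The recovered modulation lifetimes (2.202 and 2.678 ns)
match the calibration targets (2.2 and 2.7 ns) to within photon shot
noise, giving temperatures within ~0.5 °C of truth; precision tightens
with photon budget.

The same stages are available from the shell — `thermoflim simulate-flim`,
`phasor`, `calibrate`, `thermo-map`, `compare`, `biexp`, `relax`, `rdf`,
`hbonds`, `rg`, `msd`, `report`; `thermoflim show-config` prints all
defaults.

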