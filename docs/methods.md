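# Methods

## Decay model and synthetic TCSPC data

Photon arrival-time densities are modelled as period-wrapped
multi-exponential decays convolved with a Gaussian instrument response
(IRF). For lifetime τ, IRF width σ and period P, the density of one
component is the exponentially modified Gaussian folded into [0, P);
expected bin contents are computed as exact differences of the EMG
cumulative distribution summed over period wraps (truncated when the
previous-pulse tail falls below 10⁻¹², so photon conservation holds to
machine precision). There is no quadrature anywhere in the decay model.
Pre-exponential amplitudes a_i enter the mixture with photon (intensity)
fractions a_iτ_i/Σa_jτ_j; a τ → 0 component is treated as a prompt spike
carrying its amplitude as photon fraction. Counts are drawn as
independent Poisson deviates per bin with a recorded seed.

Defaults: excitation period 25 ns (40 MHz, a common TCSPC repetition
rate) with 256 bins and IRF σ = 0.1 ns. Photon budgets are free
parameters of the generator; the recovery experiments use ≥10⁵ photons
per cell (per-cell temperature noise ≈0.2–0.3 °C, far below the per-cell
biological spread they are embedded in).

The FLIM scene generator lays cells out as labelled squares, draws every
in-cell pixel from the cell's temperature-determined decay, and emits the
stack (uint16 multi-page TIFF), label mask, ground-truth table and a JSON
metadata sidecar carrying the bin width, period, IRF width, seed and
truth-calibration coefficients. Temperatures outside the declared
calibration validity range raise — there is no silent clamping.

**Ground-truth calibration.** The generator's lifetime–temperature truth
is linear, τ_M = 0.7 + 0.05·T ns (rising with temperature), declared by
default over 25–45 °C. The coefficients live in generator configuration
and metadata only; analysis code always *fits* its calibration from
(T, τ_M) points. The decay family realising a target τ_M keeps a fixed
lifetime ratio τ₂/τ₁ = 4 and equal photon fractions, solving for τ₁ by
root finding on the closed-form phasor algebra — so the ideal
(continuous-time) modulation lifetime of each synthetic cell equals its
calibration target exactly.

What the generator does **not** emulate: detector afterpulsing, pile-up,
dark counts, autofluorescence background structure, spatial lifetime
gradients within a cell, and scattering. Passing recovery tests therefore
demonstrates correctness of the estimators under ideal shot-noise
statistics, not robustness to every instrumental artefact of real FLIM.

## Phasor analysis

The transform uses bin-center time coordinates. Binning introduces a
half-bin phase and a sinc-like demodulation bias; both are common to all
decays measured with the same binning and are removed exactly by
reference calibration (complex rotation/scaling mapping the measured
reference phasor onto the ideal phasor of its known lifetime). The
harmonic defaults to 1; higher harmonics are supported.

Per-cell summaries pool pixels by photon weight: the pooled phasor is
identically the phasor of the summed histogram (linearity), which is the
photon-statistics-optimal estimator; the per-pixel SD is reported
alongside. Pixels under the photon threshold (default 100 counts) are
excluded; a cell losing all pixels is reported with an
"insufficient photons" status rather than dropped. Out-of-semicircle
phasors (noise) are flagged invalid, never clipped into range.

The bi-exponential fitter does weighted least squares (inverse Poisson
standard deviations) on the same IRF-convolved wrapped model, with free
total intensity, photon fraction and two lifetimes, log/logistic
parameterisation, and multistart initialisation around the empirical mean
arrival time. Components are reported in canonical order τ₁ ≤ τ₂; nearly
equal lifetimes (within 5% relative) collapse to a flagged
mono-exponential.

## Thermometry and statistics

Calibration curves are degree-1 or degree-2 polynomials fitted by least
squares; strict monotonicity is verified on a 512-point grid over the
validity range and violation is an error (the fix is a different degree
or range, not silent acceptance). Inversion is by monotone root finding;
lifetimes mapping outside the validity range are still inverted up to a
configurable margin (default 10 °C) with an "extrapolated" status, beyond
which they are rejected.

Group comparison: one-way ANOVA (standard sums of squares, via
`scipy.stats.f_oneway`) followed by all pairwise t tests — Welch's
unequal-variance form by default, switchable to pooled — with Holm–Šidák
step-down adjustment p_adj(i) = max_{j≤i}[1 − (1 − p_(j))^(m−j+1)].
Stars: **** p < 0.0001, *** p < 0.001, ** p < 0.005, and * for p < 0.05
(a level the source convention uses but never defines; it is rendered for
completeness). All-equal degenerate data short-circuits to F = 0, p = 1.

## Relaxation fits and the chain-length model

τ_relax is fitted by nonlinear least squares of
T(t) = T_bath + (T₀ − T_bath)e^(−t/τ), initialised from a log-linear
regression of the excess temperature. The bath temperature is fixed at
300 K by default — the solvent thermostat value — with a free-bath option
(whether the original analysis fixed it is not stated; fixing is the
better-conditioned choice on 200 ps series and both options are tested).
Non-decaying input yields a `converged=False` flag, never a spurious τ.
Synthetic series default to T₀ = 400 K, T_bath = 300 K, 200 ps duration —
the production-run conditions of the study protocol — and a recovery
accuracy of 5% at 2 K noise is verified over a 1–20 ps τ grid.

The chain-length model is an ordinary least-squares line of τ_relax
against chain length in amino acids, evaluated by default at 42 a.a.
(full-length Aβ42) with an extrapolation flag. The per-chain-length
τ_relax values behind the published linear fits are not tabulated
anywhere recomputable, so the printed 42-a.a. predictions cannot be
re-derived from printed inputs; the operator is instead verified exactly
against the closed-form normal equations.

## Spatial trajectory operators

All spatial operators use the orthorhombic minimum-image convention
(triclinic boxes are out of scope) and are tested for exact agreement
with brute-force enumeration on ≤100-atom instances, including across
periodic images.

* **g(r)** — pair-distance histogram normalised by the ideal-gas
  expectation n_pairs·V_shell/V_box per frame (self-pairs excluded when
  selections overlap); bin width defaults to 0.1 Å; r_max beyond half the
  smallest box length is an error.
* **Hydrogen bonds** — geometric criterion, donor–acceptor distance
  ≤ 3.5 Å and D–H···A angle ≥ 150° (conventional cutoffs; none are given
  in the source — both configurable). Hydrogens must carry an assigned
  donor; triplets sharing the acceptor with the donor or hydrogen are
  excluded.
* **Hydration shell** — water oxygens within 3.5 Å (closed boundary) of
  any protein heavy atom, membership frozen at the reference frame for
  downstream displacement analysis.
* **Radius of gyration** — mass-weighted, about the selection's centre of
  mass; cross-checked against MDAnalysis.
* **MSD/diffusivity** — all-time-origin MSD via the FFT autocorrelation
  identity, averaged over selected atoms; D = slope/6 over a lag window
  expressed as fractions (0.01, 0.1) of the maximum lag, converted as
  1 Å²/ps = 10⁻⁴ cm²/s. The early-lag window is used because long-lag
  all-origin MSD estimates are few and strongly correlated; for ideal
  Brownian input this estimator recovers D with ≈2% standard deviation at
  100 tracers × 1000 steps. A log-log exponent farther than 0.5 from 1
  over the window clears the `diffusive` flag (ballistic input is flagged,
  not reported as a diffusivity). Wrapped trajectories are unwrapped by
  accumulating minimum-image frame-to-frame displacements, which assumes
  no atom moves more than half a box length between frames. The
  diffusivity is reported in cm² s⁻¹ throughout (the dimensionally
  consistent reading of MSD/time).
* **Kinetic temperature** — T = 2·KE/(k_B·N_dof) with N_dof = 3N −
  n_constraints, masses in amu and velocities in Å/ps
  (k_B = 0.831446 amu Å² ps⁻² K⁻¹).

Terminus flags for the ion–termini g(r) default to the first/last residue
per chain (from the atom-flag sidecar or PDB heuristics); which atoms
define the charged termini is configurable since the original selection
is unstated.

## Recovery experiments (study conditions)

The two-group thermometry harness draws per-cell true temperatures
Normal(group mean, SEM·√30) at the published cell-averaged group means —
30.4 ± 0.5 °C (control), 33.2 ± 0.8 °C (aggregation), 40.4 ± 1.2 °C
(uncoupler) — renders 30 cells per condition per seed over three seeded
replicates at ≥10⁵ photons per cell, and reports the difference of
recovered group means. For these experiments the linear truth calibration
is declared over 5–75 °C so that the full Normal spread (>5 SD around
every group mean) lies inside the validity range; the curve itself is
unchanged. The recovered difference carries the sampling variability of
the Normal draws (SD ≈ 0.5 °C for the three-replicate mean) on top of a
pipeline bias verified to be < 0.05 °C — so agreement with the published
elevations is assessed against the measured SEM of the difference, not to
arbitrary precision.

The sensor harness simulates two groups of 30 bi-exponential decays
(10⁶ photons each; base parameters a = (0.6, 0.4), τ = (1.2, 3.5) ns,
CFP-like), shifts the long lifetime of one group so the true
amplitude-weighted mean lifetime differs by the requested offset, fits
every decay individually and reports the difference of group-mean fitted
τ_m.

Problem sizes throughout (30 cells/group, 3 replicates, 10⁶-photon fits,
100 tracers × 1000 steps) are chosen so every recovery experiment runs in
seconds at desk scale while keeping estimator noise well below the
tolerances being checked.

## Known limitations

* No real trajectories: the MD operators are validated on constructed and
  ideal-gas/Brownian fixtures, not on all-atom amyloid systems; absolute
  published values that require the original trajectories (hydration-shell
  diffusivities, Rg shrinkage, the 6.38/7.05 ps predictions) are out of
  reach by construction.
* The thermometry arm recovers *differences* under a synthetic
  calibration; absolute cell temperatures depend on the real instrument
  calibration and are not reproduced.
* Single-frequency phasor analysis resolves at most two lifetime
  components; no multi-component unmixing.
* Orthorhombic boxes only; no velocity-file standard beyond the XYZ-format
  convention documented in `trajectory.py`.
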