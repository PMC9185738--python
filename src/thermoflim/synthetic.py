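"""Synthetic generators for every input the analysis pipeline consumes.

Each generator has known ground truth and a recorded seed so downstream
recovery can be scored exactly:

* TCSPC decay histograms — bi-exponential fluorescent-polymeric-thermometer
  (FPT) decays with Gaussian IRF, period wrapping and Poisson shot noise;
* FLIM scenes — labeled cells whose per-cell ground-truth temperature sets
  the decay through a stated, invertible lifetime calibration;
* protein-chain thermal relaxation series — exponential decay of a heated
  chain (e.g. 400 K) toward the solvent bath (300 K) with Gaussian noise;
* Brownian tracers for diffusivity recovery;
* single-frame particle configurations (ideal gas, fixed pair, hydrogen-bond
  scenes) as exact fixtures for the spatial trajectory operators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import CM2_PER_S_TO_A2_PER_PS
from .decaymodel import mixture_bin_probs
from .phasor import DecayHistogram, multiexp_phasor
from .trajectory import TemperatureSeries, Trajectory, default_atoms_table

__all__ = [
    "FPTDecayModel",
    "TruthCalibration",
    "SceneConfig",
    "RelaxationTruth",
    "FLIMScene",
    "simulate_decay",
    "expected_decay",
    "biexp_model_for_temperature",
    "simulate_flim_scene",
    "simulate_relaxation_series",
    "simulate_brownian_tracers",
    "simulate_particle_config",
]


@dataclass
class FPTDecayModel:
    """Bi-exponential decay with Gaussian IRF in a periodic excitation train."""

    lifetimes: tuple[float, float]  # ns
    amplitudes: tuple[float, float]  # pre-exponential, nonnegative
    irf_sigma: float = 0.0  # ns
    period: float = 25.0  # ns (40 MHz repetition, a common TCSPC setting)
    n_bins: int = 256

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.lifetimes):
            raise ValueError("lifetimes must be positive")
        if any(a < 0 for a in self.amplitudes) or sum(self.amplitudes) <= 0:
            raise ValueError("amplitudes must be nonnegative with positive sum")
        if self.n_bins < 16:
            raise ValueError("n_bins must be at least 16")
        if self.irf_sigma < 0:
            raise ValueError("irf_sigma must be nonnegative")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def bin_width(self) -> float:
        return self.period / self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.period, self.n_bins + 1)

    def bin_probs(self) -> np.ndarray:
        return mixture_bin_probs(
            np.asarray(self.lifetimes),
            np.asarray(self.amplitudes),
            self.bin_edges,
            self.period,
            self.irf_sigma,
        )


@dataclass
class TruthCalibration:
    """Ground-truth linear map T (degC) -> tau_M (ns) used by the generator.

    The default rises with temperature (higher lifetime at higher
    temperature); coefficients are generator configuration, never baked
    into analysis code.
    """

    slope: float = 0.05  # ns per degC
    intercept: float = 0.7  # ns at 0 degC  (tau_M = 2.2 ns at 30 degC)
    t_min: float = 25.0
    t_max: float = 45.0

    def tau_at(self, T: float) -> float:
        if not (self.t_min <= T <= self.t_max):
            raise ValueError(
                f"temperature {T:.2f} degC outside calibration validity "
                f"range [{self.t_min}, {self.t_max}]"
            )
        return self.intercept + self.slope * T

    def points(self, n: int = 9) -> pd.DataFrame:
        T = np.linspace(self.t_min, self.t_max, n)
        return pd.DataFrame({"T_C": T, "tau_M_ns": self.intercept + self.slope * T})


@dataclass
class SceneConfig:
    """Layout and photon statistics of a synthetic FLIM scene."""

    shape: tuple[int, int]
    cell_temperatures: list[float]  # degC, ground truth per cell
    photons_per_pixel: float  # expected in-cell counts per pixel
    background_rate: float = 0.0  # expected background counts per pixel
    cell_size: int = 4  # cells are cell_size x cell_size squares
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if not self.cell_temperatures:
            raise ValueError("cell_temperatures must list at least one cell")

    @property
    def n_cells(self) -> int:
        return len(self.cell_temperatures)


@dataclass
class RelaxationTruth:
    """Ground truth for a protein-chain thermal relaxation series."""

    tau_relax: float  # ps
    T0: float = 400.0  # K, heated initial temperature
    T_bath: float = 300.0  # K, solvent bath
    dt: float = 0.1  # ps
    duration: float = 200.0  # ps (matches a typical production run)
    noise_sd: float = 0.0  # K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_relax <= 0:
            raise ValueError("tau_relax must be positive")
        if self.T0 <= self.T_bath:
            raise ValueError("T0 must exceed T_bath")


@dataclass
class FLIMScene:
    stack: np.ndarray  # (n_bins, ny, nx) uint16
    mask: np.ndarray  # (ny, nx) uint16 labels, 0 = background
    truth: pd.DataFrame  # cell_id, T_C, tau_M_ns
    meta: dict


def expected_decay(model: FPTDecayModel, total_photons: float) -> np.ndarray:
    """Expected (noise-free) bin contents; sums exactly to the photon budget."""
    if total_photons <= 0:
        raise ValueError("total_photons must be positive")
    return total_photons * model.bin_probs()


def simulate_decay(
    model: FPTDecayModel,
    total_photons: float,
    seed: int | np.random.Generator = 0,
    noiseless: bool = False,
) -> DecayHistogram:
    """Draw one TCSPC histogram: Poisson counts around the analytic expectation."""
    expected = expected_decay(model, total_photons)
    if noiseless:
        counts = expected
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        counts = rng.poisson(expected)
    return DecayHistogram(
        counts=counts, bin_width=model.bin_width, period=model.period
    )


def biexp_model_for_temperature(
    T: float,
    calib: TruthCalibration,
    tau_ratio: float = 4.0,
    photon_frac_short: float = 0.5,
    irf_sigma: float = 0.1,
    period: float = 25.0,
    n_bins: int = 256,
) -> FPTDecayModel:
    """Bi-exponential FPT model whose ideal phasor tau_M equals calib(T).

    The family keeps a fixed lifetime ratio tau2/tau1 and photon fraction
    and solves for tau1 so the continuous-time phasor modulation lifetime
    matches the calibration target; tau_M of the family is strictly
    monotone in tau1, so the root is unique.
    """
    target = calib.tau_at(T)
    omega = 2.0 * np.pi / period
    f1 = photon_frac_short

    def tau_m_of(tau1: float) -> float:
        taus = [tau1, tau_ratio * tau1]
        amps = [f1 / taus[0], (1.0 - f1) / taus[1]]
        g, s = multiexp_phasor(taus, amps, omega)
        return np.sqrt(1.0 / (g * g + s * s) - 1.0) / omega

    tau1 = brentq(lambda x: tau_m_of(x) - target, 1e-3, period / 2.0)
    taus = (tau1, tau_ratio * tau1)
    amps = (f1 / taus[0], (1.0 - f1) / taus[1])
    return FPTDecayModel(
        lifetimes=taus,
        amplitudes=amps,
        irf_sigma=irf_sigma,
        period=period,
        n_bins=n_bins,
    )


def simulate_flim_scene(
    config: SceneConfig,
    calib: TruthCalibration | None = None,
    irf_sigma: float = 0.1,
    period: float = 25.0,
    n_bins: int = 256,
) -> FLIMScene:
    """Render a labeled multi-cell FLIM stack with known per-cell temperatures.

    Cells are laid out on a grid; every pixel of a cell draws an independent
    Poisson decay from the cell's temperature-determined bi-exponential
    model (no silent clamping — out-of-range temperatures raise).
    """
    calib = calib or TruthCalibration()
    ny, nx = config.shape
    size = config.cell_size
    per_row = max(nx // (2 * size), 1)
    rows_needed = -(-config.n_cells // per_row)
    if rows_needed * 2 * size > ny:
        raise ValueError("scene shape too small for the requested cell count")
    rng = np.random.default_rng(config.seed)
    mask = np.zeros((ny, nx), dtype=np.uint16)
    stack = np.zeros((n_bins, ny, nx), dtype=np.uint16)
    rows = []
    for i, T in enumerate(config.cell_temperatures):
        model = biexp_model_for_temperature(
            T, calib, irf_sigma=irf_sigma, period=period, n_bins=n_bins
        )
        r0 = (i // per_row) * 2 * size + size // 2
        c0 = (i % per_row) * 2 * size + size // 2
        mask[r0 : r0 + size, c0 : c0 + size] = i + 1
        expected = expected_decay(model, config.photons_per_pixel)
        counts = rng.poisson(expected, size=(size * size, n_bins))
        stack[:, r0 : r0 + size, c0 : c0 + size] = (
            counts.T.reshape(n_bins, size, size)
        )
        rows.append(
            {"cell_id": i + 1, "T_C": T, "tau_M_ns": calib.tau_at(T)}
        )
    if config.background_rate > 0:
        bg = rng.poisson(
            config.background_rate / n_bins, size=(n_bins, ny, nx)
        )
        stack = (stack.astype(np.int64) + bg).clip(0, 65535).astype(np.uint16)
    meta = {
        "bin_width_ns": period / n_bins,
        "period_ns": period,
        "n_bins": n_bins,
        "irf_sigma_ns": irf_sigma,
        "seed": config.seed,
        "calibration": {
            "slope": calib.slope,
            "intercept": calib.intercept,
            "t_min": calib.t_min,
            "t_max": calib.t_max,
        },
    }
    return FLIMScene(stack=stack, mask=mask, truth=pd.DataFrame(rows), meta=meta)


def simulate_relaxation_series(truth: RelaxationTruth) -> TemperatureSeries:
    """Exponential chain-temperature decay toward the bath, with noise."""
    times = np.arange(0.0, truth.duration + 0.5 * truth.dt, truth.dt)
    temps = truth.T_bath + (truth.T0 - truth.T_bath) * np.exp(
        -times / truth.tau_relax
    )
    meta = {"seed": truth.seed, "tau_relax_true_ps": truth.tau_relax}
    if truth.duration < 5.0 * truth.tau_relax:
        meta["warning"] = (
            "duration below 5*tau_relax; relaxation fit may be ill-conditioned"
        )
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        temps = temps + rng.normal(0.0, truth.noise_sd, size=times.size)
    return TemperatureSeries(chain_id="chain0", times=times, temperatures=temps, meta=meta)


def simulate_brownian_tracers(
    D_cm2_s: float,
    n_tracers: int = 100,
    dt_ps: float = 1.0,
    n_steps: int = 1000,
    seed: int = 0,
    box: np.ndarray | None = None,
) -> Trajectory:
    """Independent 3-D Gaussian random walks with diffusivity D.

    Per-step per-axis displacement variance is 2 D dt (D converted from
    cm^2/s to A^2/ps internally). Coordinates are unwrapped.
    """
    if D_cm2_s < 0:
        raise ValueError("diffusivity D must be nonnegative")
    rng = np.random.default_rng(seed)
    D = D_cm2_s * CM2_PER_S_TO_A2_PER_PS
    sd = np.sqrt(2.0 * D * dt_ps)
    steps = rng.normal(0.0, sd, size=(n_steps, n_tracers, 3)) if sd > 0 else np.zeros(
        (n_steps, n_tracers, 3)
    )
    coords = np.concatenate(
        [np.zeros((1, n_tracers, 3)), np.cumsum(steps, axis=0)], axis=0
    )
    atoms = default_atoms_table(n_tracers, element="O", resname="HOH")
    atoms["is_water_oxygen"] = True
    atoms["is_protein"] = False
    return Trajectory(
        coords=coords,
        atoms=atoms,
        box=box,
        dt=dt_ps,
        meta={"seed": seed, "D_true_cm2_s": D_cm2_s},
    )


def _hbond_acceptor_position(r_da: float, angle_deg: float, d_dh: float = 1.0) -> np.ndarray:
    """Acceptor position for donor at origin, hydrogen at (d_dh, 0, 0), given
    the D-H...A angle at the hydrogen and the D-A distance."""
    theta = np.deg2rad(angle_deg)
    disc = np.cos(theta) ** 2 - 1.0 + (r_da / d_dh) ** 2
    if disc < 0:
        raise ValueError(
            f"infeasible hydrogen-bond geometry: D-A distance {r_da} with "
            f"angle {angle_deg} deg cannot be realized"
        )
    rho = d_dh * (np.cos(theta) + np.sqrt(disc))
    if rho <= 0:
        raise ValueError("infeasible hydrogen-bond geometry: acceptor collapses onto H")
    u = np.array([-np.cos(theta), np.sin(theta), 0.0])
    return np.array([d_dh, 0.0, 0.0]) + rho * u


def simulate_particle_config(
    kind: str, params: dict | None = None, seed: int = 0
) -> tuple[Trajectory, dict]:
    """Single-frame particle configurations with exact ground truth.

    kinds:
      ``ideal_gas``   — n uniform points in a periodic box (g(r) -> 1);
      ``fixed_pair``  — two tagged particles at exact separation d;
      ``hbond_scene`` — donor-H-acceptor triplets with prescribed distances
                        and angles and a known count of criterion-satisfying
                        bonds.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "ideal_gas":
        n = int(params.get("n", 1000))
        box = float(params.get("box", 20.0))
        if n < 1:
            raise ValueError("ideal_gas needs n >= 1")
        coords = rng.uniform(0.0, box, size=(1, n, 3))
        atoms = default_atoms_table(n, element="Ar", resname="GAS")
        traj = Trajectory(
            coords=coords, atoms=atoms, box=np.array([box] * 3), dt=1.0,
            meta={"seed": seed, "kind": kind},
        )
        return traj, {"density": n / box**3}
    if kind == "fixed_pair":
        d = float(params.get("d", 3.0))
        box = float(params.get("box", 20.0))
        if d >= box / 2.0:
            raise ValueError("pair separation must be below half the box length")
        coords = np.array([[[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]]])
        atoms = default_atoms_table(2, element="Ar", resname="PRT")
        traj = Trajectory(
            coords=coords, atoms=atoms, box=np.array([box] * 3), dt=1.0,
            meta={"seed": seed, "kind": kind},
        )
        return traj, {"distance": d}
    if kind == "hbond_scene":
        good = params.get("good", [(2.9, 170.0)] * 5)
        bad = params.get("bad", [(5.0, 170.0), (2.9, 100.0), (4.5, 120.0)])
        box = float(params.get("box", 60.0))
        triplets = [(r, a, True) for r, a in good] + [(r, a, False) for r, a in bad]
        coords_list, rows = [], []
        spacing = box / (len(triplets) + 1)
        for i, (r_da, angle, is_good) in enumerate(triplets):
            local = np.vstack(
                [
                    np.zeros(3),
                    np.array([1.0, 0.0, 0.0]),
                    _hbond_acceptor_position(r_da, angle),
                ]
            )
            # random rigid rotation, well-separated placement
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
                ]
            )
            origin = np.array([spacing * (i + 1)] * 3) % box
            coords_list.append(local @ rot.T + origin)
            rows.append(is_good)
        coords = np.vstack(coords_list)[None, :, :]
        n = coords.shape[1]
        atoms = default_atoms_table(n, element="O", resname="HBS")
        atoms.loc[:, "element"] = ["O", "H", "O"] * len(triplets)
        atoms["is_donor"] = [i % 3 == 0 for i in range(n)]
        atoms["is_hydrogen"] = [i % 3 == 1 for i in range(n)]
        atoms["is_acceptor"] = [i % 3 == 2 for i in range(n)]
        atoms["donor_index"] = [i - 1 if i % 3 == 1 else -1 for i in range(n)]
        traj = Trajectory(
            coords=coords, atoms=atoms, box=np.array([box] * 3), dt=1.0,
            meta={"seed": seed, "kind": kind},
        )
        return traj, {"n_true_bonds": int(sum(rows)), "triplet_is_bond": rows}
    raise ValueError(f"unknown particle configuration kind: {kind!r}")
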