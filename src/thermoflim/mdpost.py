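"""Post-processing of molecular-dynamics output for thermal-relaxation studies.

Operators mirror the analyses used to characterize heat dissipation from
amyloid peptides: instantaneous kinetic temperature of a subsystem,
exponential fits of chain-temperature relaxation toward the solvent bath
(tau_relax), a linear chain-length model with interpolation to 42 amino
acids, ion-termini radial distribution functions, geometric protein-water
hydrogen-bond counts, mass-weighted radius of gyration, hydration-shell
selection, and mean-squared-displacement diffusivity of shell waters.

All spatial operators use the orthorhombic minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .constants import A2_PER_PS_TO_CM2_PER_S, KB_AMU_A2_PS2
from .trajectory import TemperatureSeries, Trajectory

__all__ = [
    "RelaxationFit",
    "ChainLengthModel",
    "RDFResult",
    "HBondCriteria",
    "MSDResult",
    "kinetic_temperature",
    "fit_relaxation_time",
    "fit_chain_length_model",
    "minimum_image",
    "radial_distribution",
    "count_hydrogen_bonds",
    "radius_of_gyration",
    "select_hydration_shell",
    "msd_diffusivity",
]


@dataclass
class RelaxationFit:
    tau_relax: float  # ps
    T0: float  # K
    T_bath: float  # K
    residual_sd: float  # K
    converged: bool
    message: str = ""


@dataclass
class ChainLengthModel:
    slope: float  # ps per amino acid
    intercept: float  # ps
    solvent: str
    points: np.ndarray  # (n, 2) of (n_aa, tau_relax)
    prediction: float | None = None  # ps at requested chain length
    predict_at: float | None = None
    extrapolated: bool = False


@dataclass
class RDFResult:
    edges: np.ndarray  # A
    g: np.ndarray
    counts: np.ndarray  # raw pair counts per bin, summed over frames
    selection_a: str = ""
    selection_b: str = ""
    n_frames: int = 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    Donor-acceptor distance at most ``da_cutoff`` (A) and D-H...A angle at
    the hydrogen at least ``angle_cutoff`` (degrees); 3.5 A / 150 deg are
    conventional cutoffs.
    """

    da_cutoff: float = 3.5
    angle_cutoff: float = 150.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("hydrogen-bond cutoffs must be positive")


@dataclass
class MSDResult:
    lags: np.ndarray  # ps
    msd: np.ndarray  # A^2
    D: float  # cm^2/s
    fit_window: tuple[int, int]  # lag-index window used for the slope
    slope: float  # A^2/ps
    intercept: float
    diffusive: bool = True  # False when the log-log exponent is far from 1


def kinetic_temperature(
    velocities: np.ndarray, masses: np.ndarray, n_constraints: int = 0
) -> float:
    """Instantaneous temperature T = 2 KE / (k_B N_dof) of a subsystem.

    Velocities in A/ps, masses in amu; N_dof = 3 N - n_constraints.
    """
    v = np.asarray(velocities, dtype=float)
    m = np.asarray(masses, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] != m.size:
        raise ValueError("velocities must be (n_atoms, 3) matching masses")
    if m.size == 0:
        raise ValueError("cannot compute a temperature for zero atoms")
    ndof = 3 * m.size - n_constraints
    if ndof <= 0:
        raise ValueError("nonpositive number of degrees of freedom")
    twice_ke = float(np.sum(m[:, None] * v * v))
    return twice_ke / (KB_AMU_A2_PS2 * ndof)


def fit_relaxation_time(
    series: TemperatureSeries,
    fix_T_bath: float | None = 300.0,
) -> RelaxationFit:
    """Exponential relaxation fit T(t) = T_bath + (T0 - T_bath) exp(-t/tau).

    The bath temperature is fixed by default (the solvent thermostat value);
    pass ``fix_T_bath=None`` to fit it freely. Initialization comes from a
    log-linear regression of the excess temperature. A series that does not
    decay is reported with ``converged=False`` rather than a spurious tau.
    """
    t = series.times
    T = series.temperatures
    if t.size < 10:
        raise ValueError("need at least 10 samples to fit a relaxation time")
    bath0 = fix_T_bath if fix_T_bath is not None else float(np.median(T[-max(t.size // 10, 2):]))
    excess = T - bath0
    head = excess[: max(t.size // 10, 2)].mean()
    if head <= 0 or T[0] <= bath0:
        return RelaxationFit(
            tau_relax=np.nan, T0=float(T[0]), T_bath=bath0,
            residual_sd=float(np.std(T)), converged=False,
            message="series does not start above the bath temperature",
        )
    pos = excess > 0
    slope, logA = np.polyfit(t[pos], np.log(excess[pos]), 1) if pos.sum() >= 2 else (-1.0, np.log(max(head, 1e-6)))
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 5.0
    tau0 = float(np.clip(tau0, 1e-3, 10 * (t[-1] - t[0])))
    try:
        if fix_T_bath is not None:
            popt, _ = curve_fit(
                lambda tt, dT, tau: fix_T_bath + dT * np.exp(-tt / tau),
                t, T, p0=[np.exp(logA), tau0], maxfev=10000,
            )
            dT, tau = popt
            T0, bath = fix_T_bath + dT, fix_T_bath
            resid = T - (bath + dT * np.exp(-t / tau))
        else:
            popt, _ = curve_fit(
                lambda tt, bath, dT, tau: bath + dT * np.exp(-tt / tau),
                t, T, p0=[bath0, np.exp(logA), tau0], maxfev=10000,
            )
            bath, dT, tau = popt
            T0 = bath + dT
            resid = T - (bath + dT * np.exp(-t / tau))
    except RuntimeError as exc:
        return RelaxationFit(
            tau_relax=np.nan, T0=float(T[0]), T_bath=bath0,
            residual_sd=float(np.std(T)), converged=False, message=str(exc),
        )
    if tau <= 0 or dT <= 0:
        return RelaxationFit(
            tau_relax=np.nan, T0=float(T0), T_bath=float(bath),
            residual_sd=float(np.std(resid)), converged=False,
            message="fit did not find a decaying exponential",
        )
    return RelaxationFit(
        tau_relax=float(tau), T0=float(T0), T_bath=float(bath),
        residual_sd=float(np.std(resid)), converged=True,
    )


def fit_chain_length_model(
    points: np.ndarray, predict_at: float | None = 42.0, solvent: str = "H2O"
) -> ChainLengthModel:
    """Ordinary least-squares line tau_relax vs chain length (amino acids).

    ``points`` is (n, 2) of (n_aa, tau_relax ps). The fitted line is
    evaluated at ``predict_at`` (default 42 a.a., the full-length peptide),
    flagged when that length lies outside the fitted range.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (n_aa, tau_relax) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("chain lengths must include at least two distinct values")
    res = stats.linregress(x, y)
    model = ChainLengthModel(
        slope=float(res.slope), intercept=float(res.intercept),
        solvent=solvent, points=pts,
    )
    if predict_at is not None:
        model.predict_at = float(predict_at)
        model.prediction = float(res.intercept + res.slope * predict_at)
        model.extrapolated = not (x.min() <= predict_at <= x.max())
    return model


def minimum_image(vectors: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    if box is None:
        return vectors
    return vectors - box * np.round(vectors / box)


def radial_distribution(
    traj: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    r_max: float,
    bin_width: float = 0.1,
    label_a: str = "",
    label_b: str = "",
) -> RDFResult:
    """Radial distribution function g(r) between two atom selections.

    Pair distances use the orthorhombic minimum image; identical atoms
    shared by both selections are excluded as self-pairs. Normalization is
    by the ideal-gas expectation: counts / (n_AB_pairs * V_shell / V_box)
    averaged over frames, so an ideal gas tends to 1.
    """
    if traj.box is None:
        raise ValueError("radial_distribution requires a periodic box")
    sel_a = np.asarray(sel_a, int)
    sel_b = np.asarray(sel_b, int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("selections must be nonempty")
    if r_max > traj.box.min() / 2.0 + 1e-9:
        raise ValueError(
            "r_max exceeds half the smallest box length (minimum-image violation)"
        )
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    n_self = np.intersect1d(sel_a, sel_b).size
    n_pairs = sel_a.size * sel_b.size - n_self
    if n_pairs <= 0:
        raise ValueError("selections contain no distinct pairs")
    for frame in traj.coords:
        d = frame[sel_a][:, None, :] - frame[sel_b][None, :, :]
        d = minimum_image(d, traj.box)
        r = np.linalg.norm(d, axis=-1)
        if n_self:
            same = sel_a[:, None] == sel_b[None, :]
            r = r[~same]
        counts += np.histogram(r, bins=edges)[0]
    volume = float(np.prod(traj.box))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs * shell / volume * traj.n_frames
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    return RDFResult(
        edges=edges, g=g, counts=counts,
        selection_a=label_a, selection_b=label_b, n_frames=traj.n_frames,
    )


def count_hydrogen_bonds(
    frame: np.ndarray,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
    box: np.ndarray | None = None,
) -> int:
    """Count D-H...A triplets meeting the geometric criterion.

    ``donors`` and ``hydrogens`` are parallel arrays (hydrogens[i] is
    covalently bound to donors[i]); every acceptor not identical to the
    donor or hydrogen is tested. Distances/angles use the minimum image.
    """
    donors = np.asarray(donors, int)
    hydrogens = np.asarray(hydrogens, int)
    acceptors = np.asarray(acceptors, int)
    if donors.size != hydrogens.size:
        raise ValueError(
            "each hydrogen must have an assigned donor (parallel index arrays)"
        )
    if donors.size == 0 or acceptors.size == 0:
        return 0
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    # D-A distance criterion
    d_da = minimum_image(
        frame[donors][:, None, :] - frame[acceptors][None, :, :], box
    )
    r_da = np.linalg.norm(d_da, axis=-1)
    # angle at H between H->D and H->A
    h_to_d = minimum_image(frame[donors] - frame[hydrogens], box)
    h_to_a = minimum_image(
        frame[acceptors][None, :, :] - frame[hydrogens][:, None, :], box
    )
    num = np.einsum("ik,ijk->ij", h_to_d, h_to_a)
    den = (
        np.linalg.norm(h_to_d, axis=-1)[:, None]
        * np.linalg.norm(h_to_a, axis=-1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_ang = np.where(den > 0, num / den, 1.0)
    not_self = (donors[:, None] != acceptors[None, :]) & (
        hydrogens[:, None] != acceptors[None, :]
    )
    # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
    ok = (r_da <= criteria.da_cutoff) & (cos_ang <= cos_cut) & not_self
    return int(ok.sum())


def radius_of_gyration(
    frame: np.ndarray, selection: np.ndarray, masses: np.ndarray
) -> float:
    """Mass-weighted radius of gyration of a selection, in angstrom."""
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("selection is empty")
    r = np.asarray(frame, float)[selection]
    m = np.asarray(masses, float)[selection]
    mtot = m.sum()
    if mtot <= 0:
        raise ValueError("selection has zero total mass")
    com = (m[:, None] * r).sum(axis=0) / mtot
    return float(np.sqrt((m * ((r - com) ** 2).sum(axis=1)).sum() / mtot))


def select_hydration_shell(
    frame: np.ndarray,
    protein_sel: np.ndarray,
    water_oxygen_sel: np.ndarray,
    cutoff: float = 3.5,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Water oxygens within ``cutoff`` of any protein heavy atom.

    The boundary is closed (distance == cutoff is included). Membership is
    decided on the given reference frame and should be frozen for any
    downstream displacement analysis.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    protein_sel = np.asarray(protein_sel, int)
    water_oxygen_sel = np.asarray(water_oxygen_sel, int)
    if protein_sel.size == 0:
        raise ValueError("protein selection is empty")
    if water_oxygen_sel.size == 0:
        return water_oxygen_sel
    d = minimum_image(
        frame[water_oxygen_sel][:, None, :] - frame[protein_sel][None, :, :], box
    )
    r_min = np.linalg.norm(d, axis=-1).min(axis=1)
    return water_oxygen_sel[r_min <= cutoff]


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """MSD of one walker over all time origins, via the FFT autocorrelation
    identity (O(T log T))."""
    T = x.shape[0]
    nfft = 1 << (2 * T - 1).bit_length()
    sq = (x * x).sum(axis=1)
    # S2: autocorrelation of each coordinate
    f = np.fft.rfft(x, n=nfft, axis=0)
    s2 = np.fft.irfft((f * f.conj()).real.sum(axis=1), n=nfft)[:T]
    s2 /= T - np.arange(T)
    # S1 recursion
    sumsq = 2.0 * sq.sum()
    s1 = np.empty(T)
    s1[0] = sumsq / T
    for lag in range(1, T):
        sumsq -= sq[lag - 1] + sq[T - lag]
        s1[lag] = sumsq / (T - lag)
    return s1 - 2.0 * s2


def unwrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping by accumulating minimum-image displacements."""
    disp = minimum_image(np.diff(coords, axis=0), box)
    out = np.empty_like(coords)
    out[0] = coords[0]
    out[1:] = coords[0] + np.cumsum(disp, axis=0)
    return out


def msd_diffusivity(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit_window: tuple[float, float] = (0.01, 0.1),
) -> MSDResult:
    """Diffusion coefficient from the mean squared displacement.

    The MSD is averaged over all time origins (FFT algorithm) and over the
    selected atoms; D = slope/6 of a least-squares line over the lag window
    given as fractions of the maximum lag, converted to cm^2/s. A log-log
    exponent far from 1 over the window (e.g. ballistic motion, exponent 2)
    clears the ``diffusive`` flag.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least three frames for an MSD")
    coords = traj.coords
    if traj.wrapped:
        if traj.box is None:
            raise ValueError("wrapped coordinates require box information to unwrap")
        coords = unwrap_coordinates(coords, traj.box)
    sel = (
        np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    )
    if sel.size == 0:
        raise ValueError("selection is empty")
    msd = np.zeros(traj.n_frames)
    for i in sel:
        msd += _msd_fft(np.ascontiguousarray(coords[:, i, :]))
    msd /= sel.size
    msd[0] = 0.0
    lags = np.arange(traj.n_frames) * traj.dt
    i0 = max(int(fit_window[0] * (traj.n_frames - 1)), 1)
    i1 = max(int(fit_window[1] * (traj.n_frames - 1)), i0 + 2)
    i1 = min(i1, traj.n_frames - 1)
    slope, intercept = np.polyfit(lags[i0 : i1 + 1], msd[i0 : i1 + 1], 1)
    positive = msd[i0 : i1 + 1] > 0
    diffusive = True
    if positive.sum() >= 3:
        alpha = np.polyfit(
            np.log(lags[i0 : i1 + 1][positive]), np.log(msd[i0 : i1 + 1][positive]), 1
        )[0]
        diffusive = bool(abs(alpha - 1.0) < 0.5)
    elif slope <= 0:
        diffusive = False
    D = max(slope, 0.0) / 6.0 * A2_PER_PS_TO_CM2_PER_S
    return MSDResult(
        lags=lags, msd=msd, D=float(D), fit_window=(i0, i1),
        slope=float(slope), intercept=float(intercept), diffusive=diffusive,
    )
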