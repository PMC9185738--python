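"""Phasor (frequency-domain) analysis of TCSPC FLIM decays.

A decay histogram c(t) is mapped to first-harmonic Fourier coordinates

    g = sum c cos(w t) / sum c,   s = sum c sin(w t) / sum c,
    w = harmonic * 2 pi / period,

evaluated at bin centers. Mono-exponential decays lie on the universal
semicircle (g - 1/2)^2 + s^2 = 1/4; mixtures fall inside it, and the
phasor of a mixture is the photon-weighted average of the component
phasors. Phase and modulation lifetimes follow from the angle and modulus:

    tau_phi = s / (g w),   tau_M = (1/w) sqrt(1/(g^2 + s^2) - 1).

Temperature readout uses tau_M, the more temperature-sensitive of the two.

Instrumental phase and modulation bias is removed by referencing against a
standard of known mono-exponential lifetime measured on the same system
(complex rotation/scaling that maps the measured reference phasor onto its
ideal position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .decaymodel import mixture_bin_probs

__all__ = [
    "DecayHistogram",
    "Phasor",
    "LifetimePair",
    "ReferenceStandard",
    "CellPhasorSummary",
    "BiExpFit",
    "PhasorDomainError",
    "phasor_transform",
    "single_exp_phasor",
    "multiexp_phasor",
    "reference_calibrate",
    "calibration_factor",
    "lifetimes_from_phasor",
    "pixel_phasors",
    "roi_phasor_summary",
    "fit_biexponential",
]


class PhasorDomainError(ValueError):
    """Raised for phasors outside the physically meaningful domain."""


@dataclass
class DecayHistogram:
    """Photon counts per arrival-time bin for one pixel or ROI."""

    counts: np.ndarray
    bin_width: float  # ns
    period: float  # ns
    origin: float = 0.0  # time of bin-0 left edge (ns)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.bin_width <= 0 or self.period <= 0:
            raise ValueError("bin_width and period must be positive")
        if self.n_bins * self.bin_width > self.period + self.bin_width:
            raise ValueError("bins span more than one excitation period")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.origin + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def bin_edges(self) -> np.ndarray:
        return self.origin + np.arange(self.n_bins + 1) * self.bin_width

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class Phasor:
    g: float
    s: float
    harmonic: int = 1
    omega: float = 0.0  # rad/ns
    total_counts: float = 0.0

    def as_complex(self) -> complex:
        return complex(self.g, self.s)


@dataclass
class LifetimePair:
    tau_phi: float  # ns
    tau_M: float  # ns


@dataclass
class ReferenceStandard:
    """A mono-exponential standard of known lifetime, as measured."""

    lifetime: float  # ns, known
    measured: Phasor

    def __post_init__(self) -> None:
        if self.lifetime <= 0:
            raise ValueError("reference lifetime must be positive")


@dataclass
class CellPhasorSummary:
    cell_id: int
    phasor: Phasor | None
    sd_g: float
    sd_s: float
    lifetimes: LifetimePair | None
    n_pixels: int
    photons: float
    status: str = "ok"  # "ok" | "insufficient photons"


@dataclass
class BiExpFit:
    a1: float
    a2: float
    tau1: float  # ns, tau1 <= tau2
    tau2: float  # ns
    tau_m: float  # amplitude-weighted mean lifetime (a1 t1 + a2 t2)/(a1+a2)
    residual_norm: float
    converged: bool = True
    collapsed: bool = False  # degenerate two-component fit -> mono-exponential


def phasor_transform(decay: DecayHistogram, harmonic: int = 1) -> Phasor:
    """First (or higher) harmonic phasor of a decay histogram.

    Bin-center time coordinates are used; the residual half-bin phase and
    sinc modulation bias is common to all decays measured with the same
    binning and is absorbed by reference calibration.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be a positive integer")
    total = decay.total_counts
    if total <= 0:
        raise ValueError("cannot compute the phasor of an empty histogram")
    omega = harmonic * 2.0 * np.pi / decay.period
    t = decay.bin_centers
    c = decay.counts.astype(float)
    g = float(np.dot(c, np.cos(omega * t)) / total)
    s = float(np.dot(c, np.sin(omega * t)) / total)
    return Phasor(g=g, s=s, harmonic=harmonic, omega=omega, total_counts=total)


def single_exp_phasor(tau: float, omega: float) -> tuple[float, float]:
    """Ideal continuous-time phasor of a mono-exponential decay."""
    if tau < 0:
        raise ValueError("lifetime must be nonnegative")
    wt = omega * tau
    g = 1.0 / (1.0 + wt * wt)
    return g, wt * g


def multiexp_phasor(
    lifetimes: Sequence[float],
    amplitudes: Sequence[float],
    omega: float,
) -> tuple[float, float]:
    """Ideal phasor of a multi-exponential decay (pre-exponential amplitudes).

    By linearity, the mixture phasor is the photon-fraction-weighted average
    of the component phasors, with photon fractions a_i tau_i / sum a_j tau_j.
    """
    taus = np.asarray(lifetimes, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    w = amps * taus
    if w.sum() <= 0:
        raise ValueError("mixture carries no intensity")
    w = w / w.sum()
    gs = np.array([single_exp_phasor(t, omega) for t in taus])
    g, s = w @ gs
    return float(g), float(s)


def calibration_factor(ref: ReferenceStandard) -> complex:
    """Complex factor mapping the measured reference phasor to its ideal one."""
    z_meas = ref.measured.as_complex()
    if abs(z_meas) < 1e-6:
        raise ValueError("reference phasor modulus too small to calibrate against")
    g, s = single_exp_phasor(ref.lifetime, ref.measured.omega)
    return complex(g, s) / z_meas


def reference_calibrate(sample: Phasor, ref: ReferenceStandard) -> Phasor:
    """Rotate/scale a sample phasor so the reference lands on its ideal spot.

    Removes the common instrumental phase shift and demodulation (IRF and
    binning bias) from the sample phasor.
    """
    z = sample.as_complex() * calibration_factor(ref)
    return Phasor(
        g=z.real,
        s=z.imag,
        harmonic=sample.harmonic,
        omega=sample.omega,
        total_counts=sample.total_counts,
    )


def lifetimes_from_phasor(p: Phasor, tol: float = 0.02) -> LifetimePair:
    """Phase and modulation lifetimes of a phasor.

    Raises :class:`PhasorDomainError` for points outside the physical domain
    (g <= 0, s < -tol, or modulus exceeding 1 by more than ``tol``); noisy
    out-of-semicircle pixels should be flagged by the caller, never silently
    clipped into range.
    """
    if p.omega <= 0:
        raise ValueError("phasor carries no angular frequency")
    mod2 = p.g * p.g + p.s * p.s
    if p.g <= 0 or p.s < -tol or mod2 > 1.0 + tol:
        raise PhasorDomainError(
            f"phasor (g={p.g:.4f}, s={p.s:.4f}) outside the physical domain"
        )
    tau_phi = max(p.s, 0.0) / (p.g * p.omega)
    inv = 1.0 / min(mod2, 1.0) - 1.0
    tau_m = np.sqrt(max(inv, 0.0)) / p.omega
    return LifetimePair(tau_phi=float(tau_phi), tau_M=float(tau_m))


def pixel_phasors(
    stack: np.ndarray,
    bin_width: float,
    period: float,
    harmonic: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel phasor coordinates of a FLIM stack.

    ``stack`` has shape (n_bins, ny, nx). Returns (g, s, total counts) images;
    pixels with zero counts get NaN coordinates.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must have shape (n_bins, ny, nx)")
    n_bins = stack.shape[0]
    omega = harmonic * 2.0 * np.pi / period
    t = (np.arange(n_bins) + 0.5) * bin_width
    c = stack.reshape(n_bins, -1).astype(float)
    total = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (np.cos(omega * t) @ c) / total
        s = (np.sin(omega * t) @ c) / total
    shape = stack.shape[1:]
    return g.reshape(shape), s.reshape(shape), total.reshape(shape)


def roi_phasor_summary(
    stack: np.ndarray,
    mask: np.ndarray,
    bin_width: float,
    period: float,
    min_photons_per_pixel: float = 100.0,
    harmonic: int = 1,
    cal_factor: complex | None = None,
) -> list[CellPhasorSummary]:
    """Per-cell phasor summaries over a labeled mask.

    The cell mean phasor is the photon-weighted average of its pixel phasors
    (identically the phasor of the pooled decay, by linearity of the
    transform); the SD is computed over included pixel phasors. Pixels with
    fewer than ``min_photons_per_pixel`` counts are excluded; a cell with no
    remaining pixels is reported with status "insufficient photons" rather
    than dropped.
    """
    mask = np.asarray(mask)
    if mask.shape != stack.shape[1:]:
        raise ValueError("mask geometry does not match the stack")
    if min_photons_per_pixel < 0:
        raise ValueError("min_photons_per_pixel must be >= 0")
    g_img, s_img, n_img = pixel_phasors(stack, bin_width, period, harmonic)
    if cal_factor is not None:
        z = (g_img + 1j * s_img) * cal_factor
        g_img, s_img = z.real, z.imag
    omega = harmonic * 2.0 * np.pi / period
    out: list[CellPhasorSummary] = []
    for cell_id in np.unique(mask[mask > 0]):
        in_cell = mask == cell_id
        ok = in_cell & (n_img >= max(min_photons_per_pixel, 1e-300)) & (n_img > 0)
        if not np.any(ok):
            out.append(
                CellPhasorSummary(
                    cell_id=int(cell_id),
                    phasor=None,
                    sd_g=np.nan,
                    sd_s=np.nan,
                    lifetimes=None,
                    n_pixels=0,
                    photons=0.0,
                    status="insufficient photons",
                )
            )
            continue
        w = n_img[ok]
        g_pix, s_pix = g_img[ok], s_img[ok]
        photons = float(w.sum())
        g_mean = float(np.dot(w, g_pix) / photons)
        s_mean = float(np.dot(w, s_pix) / photons)
        pooled = Phasor(g_mean, s_mean, harmonic, omega, photons)
        try:
            pair = lifetimes_from_phasor(pooled)
        except PhasorDomainError:
            pair = None
        out.append(
            CellPhasorSummary(
                cell_id=int(cell_id),
                phasor=pooled,
                sd_g=float(np.std(g_pix)),
                sd_s=float(np.std(s_pix)),
                lifetimes=pair,
                n_pixels=int(ok.sum()),
                photons=photons,
                status="ok" if pair is not None else "out of domain",
            )
        )
    return out


def _biexp_model(
    params: np.ndarray, edges: np.ndarray, period: float, irf_sigma: float
) -> np.ndarray:
    amp, f1, tau1, tau2 = params
    probs = mixture_bin_probs(
        np.array([tau1, tau2]),
        np.array([f1 / tau1, (1.0 - f1) / tau2]),
        edges,
        period,
        irf_sigma,
    )
    return amp * probs


def fit_biexponential(
    decay: DecayHistogram,
    irf_sigma: float = 0.0,
    min_counts: float = 1000.0,
    n_starts: int = 4,
    collapse_rel_tol: float = 0.05,
) -> BiExpFit:
    """Weighted least-squares fit of a two-component decay.

    The model is the IRF-convolved, period-wrapped bi-exponential with free
    total intensity, photon fraction and two lifetimes; weights are inverse
    Poisson standard deviations. Multistart initialization over lifetime
    splits around the empirical mean arrival time guards against local
    minima. Components are reported in canonical order tau1 <= tau2 with
    pre-exponential amplitudes; tau_m is the amplitude-weighted mean
    lifetime. Nearly equal lifetimes collapse to a flagged mono-exponential.
    """
    total = decay.total_counts
    if total < min_counts:
        raise ValueError(
            f"histogram has {total:.0f} counts, below the fitting floor {min_counts:.0f}"
        )
    edges = decay.bin_edges
    counts = decay.counts.astype(float)
    sigma = np.sqrt(np.maximum(counts, 1.0))
    # crude scale from the empirical mean arrival time
    tbar = float(np.dot(counts, decay.bin_centers) / total)
    tbar = min(max(tbar, 0.05), decay.period)

    def residuals(q: np.ndarray) -> np.ndarray:
        amp = np.exp(q[0])
        f1 = 1.0 / (1.0 + np.exp(-q[1]))  # logistic keeps f1 in (0, 1)
        tau1, tau2 = np.exp(q[2]), np.exp(q[3])
        return (_biexp_model(np.array([amp, f1, tau1, tau2]), edges, decay.period, irf_sigma) - counts) / sigma

    best = None
    splits = [(0.5, 2.0), (0.3, 1.5), (0.7, 3.0), (0.9, 1.2)][: max(n_starts, 1)]
    for lo, hi in splits:
        q0 = np.array([np.log(total), 0.0, np.log(tbar * lo), np.log(tbar * hi)])
        try:
            sol = least_squares(residuals, q0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("bi-exponential fit failed to converge from any start")

    amp = float(np.exp(best.x[0]))
    f1 = float(1.0 / (1.0 + np.exp(-best.x[1])))
    tau_a, tau_b = float(np.exp(best.x[2])), float(np.exp(best.x[3]))
    # photon fractions -> pre-exponential amplitudes a_i ~ f_i / tau_i
    comps = sorted(
        [(tau_a, f1 / tau_a), (tau_b, (1.0 - f1) / tau_b)], key=lambda c: c[0]
    )
    (tau1, a1), (tau2, a2) = comps
    norm = a1 + a2
    a1, a2 = a1 / norm, a2 / norm
    collapsed = (tau2 - tau1) <= collapse_rel_tol * tau2
    if collapsed:
        # report the amplitude-weighted single lifetime
        tau_m = (a1 * tau1 + a2 * tau2) / (a1 + a2)
        tau1 = tau2 = tau_m
        a1, a2 = 1.0, 0.0
    tau_m = (a1 * tau1 + a2 * tau2) / (a1 + a2)
    return BiExpFit(
        a1=a1,
        a2=a2,
        tau1=tau1,
        tau2=tau2,
        tau_m=tau_m,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
        collapsed=bool(collapsed),
    )
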