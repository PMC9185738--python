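"""Lifetime-to-temperature calibration, temperature maps, and group statistics.

The modulation lifetime tau_M of the fluorescent polymeric thermometer is
mapped to temperature through a monotone polynomial calibration fitted to
measured (T, tau_M) pairs. Cell-averaged temperatures come from the pooled
per-cell phasor. Group comparisons follow a one-way ANOVA followed by
pairwise t tests with Holm-Sidak step-down multiple-comparison adjustment;
significance stars use the thresholds ** p<0.005, *** p<0.001, **** p<0.0001
(and * for p<0.05, a level the source convention leaves implicit).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .phasor import CellPhasorSummary, PhasorDomainError, lifetimes_from_phasor

__all__ = [
    "CalibrationCurve",
    "CellTemperature",
    "GroupComparison",
    "fit_calibration_curve",
    "temperature_from_lifetime",
    "temperature_map",
    "holm_sidak_adjust",
    "significance_stars",
    "anova_holm_sidak",
]


@dataclass
class CalibrationCurve:
    """Polynomial tau_M(T), strictly monotone over its validity range."""

    coeffs: np.ndarray  # ascending powers: tau = c0 + c1 T + c2 T^2 ...
    t_min: float
    t_max: float
    residual_sd: float = 0.0
    points: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        grid = np.linspace(self.t_min, self.t_max, 512)
        d = np.diff(np.polynomial.polynomial.polyval(grid, self.coeffs))
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError(
                "calibration polynomial is not strictly monotone over "
                f"[{self.t_min}, {self.t_max}]; refit with a different degree "
                "or narrow the validity range"
            )
        self.increasing = bool(d[0] > 0)

    def tau_at(self, T: float | np.ndarray) -> float | np.ndarray:
        return np.polynomial.polynomial.polyval(T, self.coeffs)

    @property
    def tau_range(self) -> tuple[float, float]:
        lo, hi = self.tau_at(self.t_min), self.tau_at(self.t_max)
        return (min(lo, hi), max(lo, hi))


@dataclass
class CellTemperature:
    cell_id: int
    temperature: float  # degC (NaN when undetermined)
    tau_M: float  # ns
    status: str = "ok"  # ok | extrapolated | insufficient photons | out of domain


@dataclass
class GroupComparison:
    labels: list[str]
    summary: pd.DataFrame  # group, n, mean, sem
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame  # group_a, group_b, t, p_raw, p_adj, stars


def fit_calibration_curve(
    points: pd.DataFrame | np.ndarray, degree: int = 2
) -> CalibrationCurve:
    """Least-squares polynomial calibration of tau_M against temperature.

    ``points`` is a DataFrame with columns ``T_C``/``tau_M_ns`` or an (n, 2)
    array of (T, tau_M). Monotonicity over the spanned temperature range is
    verified numerically; a non-monotone fit raises.
    """
    if degree not in (1, 2):
        raise ValueError("calibration degree must be 1 or 2")
    if isinstance(points, pd.DataFrame):
        T = points["T_C"].to_numpy(float)
        tau = points["tau_M_ns"].to_numpy(float)
    else:
        arr = np.asarray(points, dtype=float)
        T, tau = arr[:, 0], arr[:, 1]
    if np.unique(T).size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct temperatures for degree {degree}"
        )
    coeffs = np.polynomial.polynomial.polyfit(T, tau, degree)
    resid = tau - np.polynomial.polynomial.polyval(T, coeffs)
    dof = max(T.size - (degree + 1), 1)
    return CalibrationCurve(
        coeffs=coeffs,
        t_min=float(T.min()),
        t_max=float(T.max()),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        points=pd.DataFrame({"T_C": T, "tau_M_ns": tau}),
    )


def temperature_from_lifetime(
    curve: CalibrationCurve,
    tau_M: float,
    max_extrapolation_C: float = 10.0,
) -> tuple[float, str]:
    """Invert the calibration: tau_M -> (temperature degC, status).

    In-range lifetimes invert by monotone root finding; lifetimes mapping
    outside the validity range are still inverted (status "extrapolated") up
    to ``max_extrapolation_C`` beyond the range, after which the value is
    rejected.
    """
    lo, hi = curve.t_min - max_extrapolation_C, curve.t_max + max_extrapolation_C

    def f(T: float) -> float:
        return float(curve.tau_at(T)) - tau_M

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"tau_M = {tau_M:.4f} ns unreachable within "
            f"{max_extrapolation_C} degC of the calibration range"
        )
    T = brentq(f, lo, hi, xtol=1e-9)
    status = "ok" if curve.t_min <= T <= curve.t_max else "extrapolated"
    return float(T), status


def temperature_map(
    summaries: list[CellPhasorSummary],
    curve: CalibrationCurve,
    pixel_tau_image: np.ndarray | None = None,
    max_extrapolation_C: float = 10.0,
) -> tuple[list[CellTemperature], np.ndarray | None]:
    """Cell temperatures from pooled tau_M, plus an optional per-pixel map.

    Cells flagged upstream (insufficient photons, out-of-domain phasor)
    propagate their status with NaN temperature. The per-pixel map converts
    a tau_M image for visualization; pixels that fail inversion become NaN.
    """
    cells: list[CellTemperature] = []
    for s in summaries:
        if s.lifetimes is None:
            cells.append(
                CellTemperature(
                    cell_id=s.cell_id, temperature=np.nan, tau_M=np.nan,
                    status=s.status,
                )
            )
            continue
        try:
            T, status = temperature_from_lifetime(
                curve, s.lifetimes.tau_M, max_extrapolation_C
            )
        except ValueError:
            T, status = np.nan, "out of range"
        cells.append(
            CellTemperature(
                cell_id=s.cell_id, temperature=T, tau_M=s.lifetimes.tau_M,
                status=status,
            )
        )
    image = None
    if pixel_tau_image is not None:
        image = np.full(pixel_tau_image.shape, np.nan, dtype=np.float32)
        valid = np.isfinite(pixel_tau_image)
        for idx in zip(*np.nonzero(valid)):
            try:
                image[idx] = temperature_from_lifetime(
                    curve, float(pixel_tau_image[idx]), max_extrapolation_C
                )[0]
            except ValueError:
                pass
    return cells, image


def holm_sidak_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    With raw p-values sorted ascending p_(1) <= ... <= p_(m),
    p_adj(i) = max_{j <= i} [1 - (1 - p_(j))^(m - j + 1)], reported back in
    the original order. Adjusted values are >= raw and monotone along the
    sorted sequence.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def anova_holm_sidak(
    groups: dict[str, np.ndarray], welch: bool = True
) -> GroupComparison:
    """One-way ANOVA plus Holm-Sidak-adjusted pairwise t tests.

    Pairwise tests default to Welch's unequal-variance t (switchable to the
    pooled-variance form). Degenerate all-equal data short-circuits to
    F = 0, p = 1 with every pair not significant.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than two observations")
    summary = pd.DataFrame(
        {
            "group": labels,
            "n": [arrays[k].size for k in labels],
            "mean": [arrays[k].mean() for k in labels],
            "sem": [stats.sem(arrays[k]) for k in labels],
        }
    )
    allvals = np.concatenate([arrays[k] for k in labels])
    if np.ptp(allvals) == 0.0:
        F, p_anova = 0.0, 1.0
    else:
        F, p_anova = stats.f_oneway(*[arrays[k] for k in labels])
    rows = []
    for a, b in itertools.combinations(labels, 2):
        x, y = arrays[a], arrays[b]
        if np.ptp(np.concatenate([x, y])) == 0.0:
            t, p = 0.0, 1.0
        elif x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
            t, p = np.inf, 0.0  # distinct constants
        else:
            t, p = stats.ttest_ind(x, y, equal_var=not welch)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = holm_sidak_adjust(pairwise["p_raw"].to_numpy())
    pairwise["stars"] = pairwise["p_adj"].map(significance_stars)
    return GroupComparison(
        labels=labels,
        summary=summary,
        anova_F=float(F),
        anova_p=float(p_anova),
        pairwise=pairwise,
    )
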