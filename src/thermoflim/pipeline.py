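"""End-to-end orchestration of the two analysis arms.

``run_thermometry_pipeline`` goes FLIM stack -> per-pixel phasors ->
reference calibration -> per-cell summaries -> lifetime-to-temperature
conversion -> group statistics. ``run_relaxation_pipeline`` dispatches the
trajectory/series analyses (tau_relax fits, chain-length model, g(r),
hydrogen bonds, radius of gyration, hydration-shell MSD diffusivity).

Every run is driven by a JSON-serializable :class:`RunConfig`; the resolved
config and its hash are written next to the outputs, and output CSVs carry
the hash in a leading comment line so a report can be tied to its exact
configuration. Reruns with identical config and inputs reproduce identical
tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from . import mdpost
from .experiments import matched_reference
from .phasor import calibration_factor, pixel_phasors, roi_phasor_summary
from .thermometry import (
    anova_holm_sidak,
    fit_calibration_curve,
    temperature_map,
)
from .trajectory import read_temperature_series, read_trajectory

__all__ = ["RunConfig", "RunReport", "run_thermometry_pipeline", "run_relaxation_pipeline"]

logger = logging.getLogger("thermoflim")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    kind: str  # flim_thermometry | sensor_lifetime | md_relaxation
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "run_out"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    kind: str
    config_hash: str
    version: str
    stages: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def _prepare(config: RunConfig) -> tuple[Path, RunReport]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    report = RunReport(
        kind=config.kind, config_hash=config.config_hash, version=__version__
    )
    return outdir, report


def run_thermometry_pipeline(config: RunConfig) -> RunReport:
    """Execute phasor -> calibrate -> summarize -> temperature -> group stats."""
    outdir, report = _prepare(config)
    p = config.params
    stage = "read inputs"
    try:
        stack, meta = fio.read_flim_stack(config.inputs["stack"])
        mask = fio.read_mask(config.inputs["mask"])
        calib_df = fio.read_calibration_csv(config.inputs["calibration"])
    except Exception as exc:  # noqa: BLE001 - abort naming the failing stage
        raise RuntimeError(f"thermometry pipeline failed at stage {stage!r}: {exc}") from exc
    report.stages.append({"stage": stage, "n_bins": int(stack.shape[0]),
                          "n_cells_in_mask": int(np.unique(mask[mask > 0]).size)})

    stage = "phasor + reference calibration"
    try:
        ref_lifetime = p.get("reference_lifetime_ns", 2.5)
        ref = matched_reference(
            ref_lifetime,
            meta.get("irf_sigma_ns", 0.0),
            meta["period_ns"],
            int(meta.get("n_bins", stack.shape[0])),
        )
        factor = calibration_factor(ref)
        g_img, s_img, n_img = pixel_phasors(
            stack, meta["bin_width_ns"], meta["period_ns"],
            harmonic=p.get("harmonic", 1),
        )
        z = (g_img + 1j * s_img) * factor
        summaries = roi_phasor_summary(
            stack, mask, meta["bin_width_ns"], meta["period_ns"],
            min_photons_per_pixel=p.get("min_photons_per_pixel", 100.0),
            harmonic=p.get("harmonic", 1), cal_factor=factor,
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"thermometry pipeline failed at stage {stage!r}: {exc}") from exc
    report.stages.append({"stage": stage, "n_cells": len(summaries)})

    stage = "temperature conversion"
    try:
        curve = fit_calibration_curve(calib_df, degree=p.get("calibration_degree", 2))
        omega = p.get("harmonic", 1) * 2.0 * np.pi / meta["period_ns"]
        mod2 = z.real**2 + z.imag**2
        with np.errstate(invalid="ignore", divide="ignore"):
            tau_img = np.sqrt(np.maximum(1.0 / mod2 - 1.0, 0.0)) / omega
        tau_img[(n_img < p.get("min_photons_per_pixel", 100.0)) | (mod2 > 1.0) | (z.real <= 0)] = np.nan
        cells, temp_img = temperature_map(summaries, curve, pixel_tau_image=tau_img)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"thermometry pipeline failed at stage {stage!r}: {exc}") from exc
    report.stages.append(
        {"stage": stage,
         "n_ok": sum(c.status == "ok" for c in cells),
         "n_flagged": sum(c.status != "ok" for c in cells)}
    )

    summary_df = pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in summaries],
            "g": [s.phasor.g if s.phasor else np.nan for s in summaries],
            "s": [s.phasor.s if s.phasor else np.nan for s in summaries],
            "sd_g": [s.sd_g for s in summaries],
            "sd_s": [s.sd_s for s in summaries],
            "tau_phi_ns": [s.lifetimes.tau_phi if s.lifetimes else np.nan for s in summaries],
            "tau_M_ns": [s.lifetimes.tau_M if s.lifetimes else np.nan for s in summaries],
            "n_pixels": [s.n_pixels for s in summaries],
            "photons": [s.photons for s in summaries],
            "status": [s.status for s in summaries],
        }
    )
    cells_df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "T_C": [c.temperature for c in cells],
            "tau_M_ns": [c.tau_M for c in cells],
            "status": [c.status for c in cells],
        }
    )
    _write_csv(summary_df, outdir / "cell_summaries.csv", config.config_hash)
    _write_csv(cells_df, outdir / "cell_temperatures.csv", config.config_hash)
    fio.write_temperature_image(temp_img, outdir / "temperature_map.tif")
    report.outputs = {
        "cell_summaries": str(outdir / "cell_summaries.csv"),
        "cell_temperatures": str(outdir / "cell_temperatures.csv"),
        "temperature_map": str(outdir / "temperature_map.tif"),
    }

    if "groups" in config.inputs:
        stage = "group statistics"
        try:
            groups_df = pd.read_csv(config.inputs["groups"], comment="#")
            merged = cells_df.merge(groups_df, on="cell_id")
            merged = merged[np.isfinite(merged["T_C"])]
            values = {
                str(k): v["T_C"].to_numpy() for k, v in merged.groupby("group")
            }
            if len(values) >= 2:
                comp = anova_holm_sidak(values)
                comp_df = comp.pairwise.copy()
                comp_df["anova_F"] = comp.anova_F
                comp_df["anova_p"] = comp.anova_p
                _write_csv(comp_df, outdir / "comparison.csv", config.config_hash)
                _write_csv(comp.summary, outdir / "group_summary.csv", config.config_hash)
                report.outputs["comparison"] = str(outdir / "comparison.csv")
            report.stages.append({"stage": stage, "n_groups": len(values)})
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"thermometry pipeline failed at stage {stage!r}: {exc}"
            ) from exc

    report.save(outdir / "report.json")
    logger.info("thermometry pipeline complete: %d cells", len(cells))
    return report


def run_relaxation_pipeline(config: RunConfig) -> RunReport:
    """Execute the requested trajectory/series analyses, isolating failures.

    Analyses are selected by the inputs present and ``params['analyses']``
    (default: everything applicable). A failing analysis records its error
    and the rest still run.
    """
    outdir, report = _prepare(config)
    p = config.params
    requested = set(p.get("analyses", ["tau_relax", "chain_model", "rdf",
                                       "hbonds", "rg", "msd"]))

    if "series" in config.inputs and "tau_relax" in requested:
        try:
            series = read_temperature_series(config.inputs["series"])
            rows = []
            for s in series:
                fit = mdpost.fit_relaxation_time(
                    s, fix_T_bath=p.get("fix_T_bath", 300.0)
                )
                rows.append(
                    {"chain_id": s.chain_id, "tau_relax_ps": fit.tau_relax,
                     "T0_K": fit.T0, "T_bath_K": fit.T_bath,
                     "residual_sd_K": fit.residual_sd, "converged": fit.converged}
                )
            df = pd.DataFrame(rows)
            _write_csv(df, outdir / "tau_relax.csv", config.config_hash)
            report.outputs["tau_relax"] = str(outdir / "tau_relax.csv")
            report.stages.append({"stage": "tau_relax", "n_chains": len(rows)})
        except Exception as exc:  # noqa: BLE001
            report.errors["tau_relax"] = str(exc)

    if "chain_points" in config.inputs and "chain_model" in requested:
        try:
            pts = pd.read_csv(config.inputs["chain_points"], comment="#")
            model = mdpost.fit_chain_length_model(
                pts[["n_aa", "tau_relax_ps"]].to_numpy(),
                predict_at=p.get("predict_at_aa", 42.0),
                solvent=p.get("solvent", "H2O"),
            )
            out = {
                "slope_ps_per_aa": model.slope,
                "intercept_ps": model.intercept,
                "solvent": model.solvent,
                "predict_at_aa": model.predict_at,
                "tau_relax_predicted_ps": model.prediction,
                "extrapolated": model.extrapolated,
                "config_hash": config.config_hash,
            }
            (outdir / "chain_model.json").write_text(json.dumps(out, indent=1))
            report.outputs["chain_model"] = str(outdir / "chain_model.json")
            report.stages.append({"stage": "chain_model", "n_points": len(pts)})
        except Exception as exc:  # noqa: BLE001
            report.errors["chain_model"] = str(exc)

    traj = None
    if "pdb" in config.inputs and "xyz" in config.inputs:
        traj = read_trajectory(
            config.inputs["pdb"], config.inputs["xyz"],
            box_json=config.inputs.get("box"),
            flags_json=config.inputs.get("flags"),
            vel_xyz=config.inputs.get("velocities"),
        )
        report.stages.append(
            {"stage": "read trajectory", "n_frames": traj.n_frames,
             "n_atoms": traj.n_atoms}
        )

    if traj is not None:
        frame0 = traj.coords[0]
        masses = traj.atoms["mass"].to_numpy()
        if "rdf" in requested and traj.box is not None:
            try:
                sel_a = traj.select(p.get("rdf_sel_a", "is_n_terminus"))
                sel_b = np.flatnonzero(
                    (traj.atoms["ion"] == p.get("rdf_ion", "Cl")).to_numpy()
                )
                if sel_b.size == 0:
                    sel_b = traj.select("is_acceptor") if traj.atoms["is_acceptor"].any() else np.arange(traj.n_atoms)
                r_max = p.get("rdf_r_max", float(traj.box.min()) / 2.0)
                rdf = mdpost.radial_distribution(
                    traj, sel_a, sel_b, r_max=r_max,
                    bin_width=p.get("rdf_bin_width", 0.1),
                )
                df = pd.DataFrame({"r_A": rdf.centers, "g": rdf.g, "count": rdf.counts})
                _write_csv(df, outdir / "rdf.csv", config.config_hash)
                report.outputs["rdf"] = str(outdir / "rdf.csv")
            except Exception as exc:  # noqa: BLE001
                report.errors["rdf"] = str(exc)
        if "hbonds" in requested:
            try:
                hyd = traj.select("is_hydrogen")
                hyd = hyd[traj.atoms["donor_index"].to_numpy()[hyd] >= 0]
                donors = traj.atoms["donor_index"].to_numpy()[hyd]
                criteria = mdpost.HBondCriteria(
                    da_cutoff=p.get("hbond_da_cutoff", 3.5),
                    angle_cutoff=p.get("hbond_angle_cutoff", 150.0),
                )
                rows = []
                for fi, frame in enumerate(traj.coords):
                    n = mdpost.count_hydrogen_bonds(
                        frame, donors, hyd, traj.select("is_acceptor"),
                        criteria, traj.box,
                    )
                    rows.append({"frame": fi, "n_hbonds": n})
                _write_csv(pd.DataFrame(rows), outdir / "hbonds.csv", config.config_hash)
                report.outputs["hbonds"] = str(outdir / "hbonds.csv")
            except Exception as exc:  # noqa: BLE001
                report.errors["hbonds"] = str(exc)
        if "rg" in requested:
            try:
                sel = traj.select("is_protein")
                rows = [
                    {"frame": fi,
                     "rg_A": mdpost.radius_of_gyration(frame, sel, masses)}
                    for fi, frame in enumerate(traj.coords)
                ]
                _write_csv(pd.DataFrame(rows), outdir / "rg.csv", config.config_hash)
                report.outputs["rg"] = str(outdir / "rg.csv")
            except Exception as exc:  # noqa: BLE001
                report.errors["rg"] = str(exc)
        if "msd" in requested and traj.n_frames >= 3:
            try:
                waters = traj.select("is_water_oxygen")
                if waters.size and traj.atoms["is_protein"].any() and p.get("msd_shell", False):
                    waters = mdpost.select_hydration_shell(
                        frame0, traj.select("is_protein"), waters,
                        cutoff=p.get("shell_cutoff", 3.5), box=traj.box,
                    )
                sel = waters if waters.size else None
                msd = mdpost.msd_diffusivity(
                    traj, sel, fit_window=tuple(p.get("msd_fit_window", (0.01, 0.1)))
                )
                df = pd.DataFrame({"lag_ps": msd.lags, "msd_A2": msd.msd})
                _write_csv(df, outdir / "msd.csv", config.config_hash)
                (outdir / "msd_fit.json").write_text(json.dumps(
                    {"D_cm2_s": msd.D, "slope_A2_ps": msd.slope,
                     "diffusive": msd.diffusive, "fit_window": list(msd.fit_window),
                     "config_hash": config.config_hash}, indent=1))
                report.outputs["msd"] = str(outdir / "msd.csv")
            except Exception as exc:  # noqa: BLE001
                report.errors["msd"] = str(exc)

    report.save(outdir / "report.json")
    logger.info(
        "relaxation pipeline complete: %d outputs, %d errors",
        len(report.outputs), len(report.errors),
    )
    return report
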