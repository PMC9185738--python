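"""Trajectory container and on-disk formats (PDB topology + XYZ frames).

A :class:`Trajectory` holds frames of coordinates in angstrom (optionally
velocities in A/ps), an orthorhombic periodic box, the frame spacing in ps,
and a per-atom metadata table carrying the role flags the analysis
operators select on (protein, water oxygen, K+/Cl- ion, chain termini,
hydrogen-bond donor/hydrogen/acceptor).

On disk a trajectory is a PDB file (topology, written/read with
MDAnalysis), a multi-frame XYZ file (coordinates, A), an optional XYZ-format
velocities file (A/ps), a ``box.json`` with box lengths and frame spacing,
and a ``flags.json`` sidecar with the atom role table. When no sidecar is
present, roles are inferred from residue/element heuristics (HOH/SOL/TIP*
water, K/CL ions, everything else protein; termini from first/last residue
per chain).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TemperatureSeries",
    "default_atoms_table",
    "write_trajectory",
    "read_trajectory",
    "read_temperature_series",
    "write_temperature_series",
]

_FLAG_COLUMNS = [
    "is_protein",
    "is_water_oxygen",
    "is_c_terminus",
    "is_n_terminus",
    "is_donor",
    "is_acceptor",
    "is_hydrogen",
]

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "K": 39.098, "CL": 35.45, "AR": 39.948, "NA": 22.99,
}


def default_atoms_table(
    n: int, element: str = "C", resname: str = "UNK", chain_id: str = "A"
) -> pd.DataFrame:
    """A fresh atom table with neutral flags, one residue per atom."""
    mass = _ELEMENT_MASSES.get(element.upper(), 12.011)
    df = pd.DataFrame(
        {
            "name": [element] * n,
            "element": [element] * n,
            "mass": [mass] * n,
            "chain_id": [chain_id] * n,
            "resid": np.arange(1, n + 1),
            "resname": [resname] * n,
            "ion": [""] * n,
            "donor_index": [-1] * n,
        }
    )
    for col in _FLAG_COLUMNS:
        df[col] = False
    df["is_protein"] = True
    return df


@dataclass
class Trajectory:
    coords: np.ndarray  # (n_frames, n_atoms, 3), A
    atoms: pd.DataFrame
    box: np.ndarray | None = None  # (3,) orthorhombic lengths, A
    dt: float = 1.0  # ps between frames
    velocities: np.ndarray | None = None  # (n_frames, n_atoms, 3), A/ps
    wrapped: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table size does not match coordinate frames")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coords.shape:
                raise ValueError("velocities must match coords in shape")
        if np.any(self.atoms["mass"].to_numpy() <= 0):
            raise ValueError("atom masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, flag: str) -> np.ndarray:
        """Indices of atoms whose boolean flag column is set."""
        return np.flatnonzero(self.atoms[flag].to_numpy())


@dataclass
class TemperatureSeries:
    """Instantaneous temperature of one chain over time."""

    chain_id: str
    times: np.ndarray  # ps, strictly increasing
    temperatures: np.ndarray  # K
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.times.shape != self.temperatures.shape:
            raise ValueError("times and temperatures must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _universe_from(traj: Trajectory, frames: np.ndarray):
    import MDAnalysis as mda

    n = traj.n_atoms
    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
    )
    atoms = traj.atoms
    u.add_TopologyAttr("names", atoms["name"].to_list())
    u.add_TopologyAttr("elements", atoms["element"].to_list())
    u.add_TopologyAttr("resnames", atoms["resname"].to_list())
    u.add_TopologyAttr("resids", atoms["resid"].to_numpy())
    u.load_new(np.ascontiguousarray(frames, dtype=np.float32), order="fac")
    return u


def write_trajectory(traj: Trajectory, outdir: str | Path, prefix: str = "traj") -> dict:
    """Write PDB + XYZ (+velocities XYZ) + box.json + flags.json; returns paths."""
    import MDAnalysis as mda

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": outdir / f"{prefix}.pdb",
        "xyz": outdir / f"{prefix}.xyz",
        "box": outdir / f"{prefix}.box.json",
        "flags": outdir / f"{prefix}.flags.json",
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = _universe_from(traj, traj.coords)
        u.atoms.write(str(paths["pdb"]))
        with mda.Writer(str(paths["xyz"]), traj.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
        if traj.velocities is not None:
            paths["vel"] = outdir / f"{prefix}.vel.xyz"
            uv = _universe_from(traj, traj.velocities)
            with mda.Writer(str(paths["vel"]), traj.n_atoms) as w:
                for _ in uv.trajectory:
                    w.write(uv.atoms)
    box = None if traj.box is None else traj.box.tolist()
    paths["box"].write_text(
        json.dumps({"box_A": box, "dt_ps": traj.dt, "wrapped": traj.wrapped,
                    "meta": traj.meta}, indent=1)
    )
    flags = traj.atoms.to_dict(orient="list")
    paths["flags"].write_text(json.dumps(flags, indent=1))
    return paths


def _heuristic_flags(atoms: pd.DataFrame) -> pd.DataFrame:
    water_res = {"HOH", "SOL", "WAT", "TIP", "TIP3", "TIP4"}
    atoms = atoms.copy()
    resname = atoms["resname"].str.upper()
    element = atoms["element"].str.upper()
    is_water = resname.isin(water_res)
    atoms["is_water_oxygen"] = is_water & (element == "O")
    atoms["ion"] = np.select(
        [resname.isin({"K", "K+", "POT"}), resname.isin({"CL", "CL-", "CLA"})],
        ["K", "Cl"],
        default="",
    )
    atoms["is_protein"] = ~is_water & (atoms["ion"] == "")
    atoms["is_hydrogen"] = element == "H"
    for col in ["is_c_terminus", "is_n_terminus", "is_donor", "is_acceptor"]:
        atoms[col] = False
    atoms["donor_index"] = -1
    for _, idx in atoms.groupby("chain_id").groups.items():
        sub = atoms.loc[idx]
        prot = sub[sub["is_protein"]]
        if len(prot):
            atoms.loc[prot.index[prot["resid"] == prot["resid"].min()], "is_n_terminus"] = True
            atoms.loc[prot.index[prot["resid"] == prot["resid"].max()], "is_c_terminus"] = True
    return atoms


def read_trajectory(
    pdb: str | Path,
    xyz: str | Path,
    box_json: str | Path | None = None,
    flags_json: str | Path | None = None,
    vel_xyz: str | Path | None = None,
    dt: float | None = None,
) -> Trajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb), str(xyz))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        velocities = None
        if vel_xyz is not None:
            uv = mda.Universe(str(pdb), str(vel_xyz))
            velocities = np.array([uv.atoms.positions.copy() for _ in uv.trajectory])
    box = None
    wrapped = False
    meta: dict = {}
    file_dt = 1.0
    if box_json is not None:
        info = json.loads(Path(box_json).read_text())
        box = None if info.get("box_A") is None else np.asarray(info["box_A"])
        file_dt = float(info.get("dt_ps", 1.0))
        wrapped = bool(info.get("wrapped", False))
        meta = info.get("meta", {})
    if flags_json is not None:
        atoms = pd.DataFrame(json.loads(Path(flags_json).read_text()))
    else:
        names = [a.name for a in u.atoms]
        elements = [
            getattr(a, "element", "") or a.name[:1] for a in u.atoms
        ]
        atoms = pd.DataFrame(
            {
                "name": names,
                "element": elements,
                "mass": [
                    _ELEMENT_MASSES.get(e.upper(), 12.011) for e in elements
                ],
                "chain_id": [getattr(a, "segid", "A") or "A" for a in u.atoms],
                "resid": [a.resid for a in u.atoms],
                "resname": [a.resname for a in u.atoms],
            }
        )
        atoms = _heuristic_flags(atoms)
    return Trajectory(
        coords=coords,
        atoms=atoms,
        box=box,
        dt=dt if dt is not None else file_dt,
        velocities=velocities,
        wrapped=wrapped,
        meta=meta,
    )


def write_temperature_series(series: list[TemperatureSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"t_ps": s.times, "T_K": s.temperatures, "chain_id": s.chain_id}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_temperature_series(path: str | Path) -> list[TemperatureSeries]:
    df = pd.read_csv(path)
    out = []
    for chain_id, sub in df.groupby("chain_id", sort=False):
        sub = sub.sort_values("t_ps")
        out.append(
            TemperatureSeries(
                chain_id=str(chain_id),
                times=sub["t_ps"].to_numpy(),
                temperatures=sub["T_K"].to_numpy(),
            )
        )
    return out
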