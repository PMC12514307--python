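"""Built-in per-frame observable calculators and prediction-table ingestion.

Chemical-shift and SAXS prediction engines are external tools; their output
is ingested as precomputed per-frame matrices (see ``load_precomputed``).
Only geometry-level observables a reweighting workflow needs directly are
computed here: Karplus scalar couplings from backbone dihedrals, radius of
gyration, and pairwise Calpha distance features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .ensemble import ObservableBlock

__all__ = [
    "KarplusCoefficients",
    "CoordinateEnsemble",
    "karplus_j",
    "radius_of_gyration",
    "ca_distance_features",
    "load_precomputed",
    "read_pdb_ca",
    "read_xyz_table",
    "fit_saxs_scale",
]

log = logging.getLogger(__name__)


@dataclass
class KarplusCoefficients:
    """A cos^2 + B cos + C (Hz) with the phase offset applied to phi.

    Default offset -60 degrees, the convention for 3J(HN,HA) couplings.
    """

    A: float = 7.09
    B: float = -1.42
    C: float = 1.55
    phase_offset: float = -60.0


@dataclass
class CoordinateEnsemble:
    """N frames of n_atoms 3D coordinates in Angstrom."""

    coordinates: np.ndarray                      # (N, n_atoms, 3)
    atom_labels: list[tuple[int, str]] = field(default_factory=list)
    masses: np.ndarray | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (N, n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.size != self.n_atoms:
                raise ValueError("masses length must equal n_atoms")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


def karplus_j(phi_angles, coeffs: KarplusCoefficients | None = None) -> np.ndarray:
    """3J couplings (Hz) from backbone phi dihedrals (degrees) via the Karplus curve."""
    if coeffs is None:
        coeffs = KarplusCoefficients()
        log.info(
            "karplus_j defaults: A=%.3f B=%.3f C=%.3f offset=%.1f deg",
            coeffs.A, coeffs.B, coeffs.C, coeffs.phase_offset,
        )
    theta = np.deg2rad(np.asarray(phi_angles, dtype=float) + coeffs.phase_offset)
    c = np.cos(theta)
    return coeffs.A * c**2 + coeffs.B * c + coeffs.C


def radius_of_gyration(coords, masses=None) -> np.ndarray | float:
    """Mass-weighted radius of gyration (Angstrom).

    Accepts a single frame (n_atoms, 3) or a stack (N, n_atoms, 3); returns
    a scalar or a per-frame vector accordingly.
    """
    x = np.asarray(coords, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    n_atoms = x.shape[1]
    if n_atoms < 2:
        raise ValueError("radius of gyration needs at least 2 atoms")
    m = np.ones(n_atoms) if masses is None else np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (x * m[None, :, None]).sum(axis=1) / total
    d2 = ((x - com[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt((d2 * m[None, :]).sum(axis=1) / total)
    return float(rg[0]) if single else rg


def ca_distance_features(coords) -> np.ndarray:
    """Pairwise Calpha-Calpha distances, lexicographic (i, j) order with i < j.

    Accepts (n_ca, 3) for one frame or (N, n_ca, 3); returns a vector of
    length n(n-1)/2 or an (N, n(n-1)/2) matrix.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim == 2:
        if x.shape[0] < 2:
            raise ValueError("need at least 2 Calpha atoms")
        return pdist(x)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 Calpha atoms")
    return np.stack([pdist(f) for f in x])


def _read_table(path) -> pd.DataFrame:
    """TSV/CSV reader with bit-exact float parsing (delimiter sniffed)."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_precomputed(table_path, metadata_path) -> ObservableBlock:
    """Read a per-frame prediction table + metadata table into one block.

    Table: delimited (TSV/CSV autodetected), first column the frame index,
    remaining columns one observable each.  Metadata: columns
    ``observable_id``, ``data_type``, ``exp_value`` and optionally
    ``exp_error``, ``units``; row order matches the table's columns.
    """
    table = _read_table(table_path)
    meta = _read_table(metadata_path)

    required = {"observable_id", "data_type", "exp_value"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_path}: missing metadata columns {sorted(missing)}")

    obs_cols = list(table.columns[1:])
    if len(obs_cols) != len(meta):
        raise ValueError(
            f"{table_path}: {len(obs_cols)} observable columns but "
            f"{len(meta)} metadata rows"
        )
    ids = meta["observable_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"{metadata_path}: duplicate observable ids")
    types = meta["data_type"].unique()
    if len(types) != 1:
        raise ValueError(
            f"{metadata_path}: one block must hold one data_type, got {list(types)}"
        )

    values = table[obs_cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        bad_rows = np.flatnonzero(~np.isfinite(values).all(axis=1)) + 2  # 1-based + header
        raise ValueError(f"{table_path}: non-finite values at lines {bad_rows.tolist()}")

    exp_error = (
        meta["exp_error"].to_numpy(dtype=float) if "exp_error" in meta.columns else None
    )
    units = str(meta["units"].iloc[0]) if "units" in meta.columns else ""
    return ObservableBlock(
        data_type=str(types[0]),
        predictions=values,
        exp_values=meta["exp_value"].to_numpy(dtype=float),
        observable_ids=ids,
        exp_error=exp_error,
        units=units,
    )


def write_precomputed(block: ObservableBlock, table_path, metadata_path) -> None:
    """Inverse of load_precomputed (full double precision)."""
    df = pd.DataFrame(block.predictions, columns=block.observable_ids)
    df.insert(0, "frame", np.arange(block.n_frames))
    df.to_csv(table_path, sep="\t", index=False, float_format="%.17g")
    meta = pd.DataFrame(
        {
            "observable_id": block.observable_ids,
            "data_type": block.data_type,
            "exp_value": block.exp_values,
        }
    )
    if block.exp_error is not None:
        meta["exp_error"] = block.exp_error
    if block.units:
        meta["units"] = block.units
    meta.to_csv(metadata_path, sep="\t", index=False, float_format="%.17g")


def read_pdb_ca(path) -> CoordinateEnsemble:
    """Calpha coordinates from a multi-model (MODEL/ENDMDL) PDB file."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    frames = []
    labels: list[tuple[int, str]] = []
    for model in structure:
        xyz = []
        lab = []
        for chain in model:
            for res in chain:
                if "CA" in res:
                    xyz.append(res["CA"].coord)
                    lab.append((res.id[1], "CA"))
        frames.append(np.asarray(xyz, dtype=float))
        if not labels:
            labels = lab
    if not frames:
        raise ValueError(f"{path}: no models found")
    n_ca = {f.shape[0] for f in frames}
    if len(n_ca) != 1:
        raise ValueError(f"{path}: inconsistent Calpha counts across models: {n_ca}")
    return CoordinateEnsemble(np.stack(frames), atom_labels=labels)


def read_xyz_table(path) -> CoordinateEnsemble:
    """Coordinates from a plain table with columns frame, residue, x, y, z (Angstrom)."""
    df = _read_table(path)
    needed = ["frame", "residue", "x", "y", "z"]
    if list(df.columns[:5]) != needed:
        raise ValueError(f"{path}: expected columns {needed}, got {list(df.columns)}")
    frames = []
    labels = None
    for _, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("residue")
        frames.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
        if labels is None:
            labels = [(int(r), "CA") for r in grp["residue"]]
    return CoordinateEnsemble(np.stack(frames), atom_labels=labels or [])


def fit_saxs_scale(exp_intensities, prior_average) -> float:
    """Least-squares scalar mapping experimental intensities onto the prediction scale.

    Applied once before calibration, never inside the optimizer.
    """
    e = np.asarray(exp_intensities, dtype=float)
    p = np.asarray(prior_average, dtype=float)
    denom = float(e @ e)
    if denom == 0:
        raise ValueError("all-zero experimental intensities")
    return float(p @ e / denom)
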