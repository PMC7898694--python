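"""File formats, run configuration and provenance.

On disk the pipeline speaks plain formats: NIfTI for signal volumes,
masks and parameter maps (affines passed through untouched),
whitespace-delimited text for acquisition tables, and CSV for component
ensembles, cluster summaries and test reports.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .mc_inversion import (
    BootstrapSolution,
    InversionConfig,
    VoxelEnsemble,
)
from .tensor_model import AcquisitionScheme, ComponentSet, cartesian_to_spherical

__all__ = [
    "RunConfig",
    "write_acquisition_table",
    "read_acquisition_table",
    "read_btensor_table",
    "read_dataset",
    "write_signal_volume",
    "ensemble_to_frame",
    "frame_to_ensemble",
    "write_ensembles",
    "read_ensembles",
    "write_maps",
    "write_provenance",
]

ACQ_COLUMNS = ("b", "b_delta", "theta", "phi", "tr", "te")


@dataclass
class RunConfig:
    """End-to-end run settings, loadable from YAML."""

    signal_path: str = ""
    acquisition_path: str = ""
    mask_path: str = ""
    output_dir: str = "."
    inversion: InversionConfig = field(default_factory=InversionConfig)
    dc_deg: float = 20.0
    odf_subdivisions: int = 4
    odf_kappa: float | None = None
    seed: int = 0
    n_workers: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inv = raw.pop("inversion", {})
        cfg = cls(**raw)
        cfg.inversion = InversionConfig(**inv)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# -- acquisition tables ------------------------------------------------

def write_acquisition_table(scheme: AcquisitionScheme, path) -> None:
    """One row per measurement, columns (b, b_delta, theta, phi, tr, te)."""
    scheme.to_frame().to_csv(path, sep=" ", index=False, float_format="%.10g")


def read_acquisition_table(path) -> AcquisitionScheme:
    df = pd.read_csv(path, sep=r"\s+")
    missing = set(ACQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"acquisition table misses columns: {sorted(missing)}")
    return AcquisitionScheme.from_frame(df)


def read_btensor_table(path, tr=None, te=None, axisym_tol: float = 1e-6):
    """Full 3x3 b-tensors in 6-column text (bxx byy bzz bxy bxz byz).

    Each row is eigendecomposed and converted to (b, b_delta,
    orientation); rows whose middle eigenvalue is not within
    ``axisym_tol * b`` of one of the extremes are rejected as
    non-axisymmetric.  Timing columns tr/te may be in the file (columns
    7-8) or supplied as arrays/scalars.
    """
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape[1] >= 8 and tr is None and te is None:
        tr = raw[:, 6]
        te = raw[:, 7]
    if tr is None or te is None:
        raise ValueError("tr and te must come from the file or the caller")

    b_out, bd_out, th_out, ph_out = [], [], [], []
    for row_index, row in enumerate(raw):
        bxx, byy, bzz, bxy, bxz, byz = row[:6]
        bt = np.array([[bxx, bxy, bxz], [bxy, byy, byz], [bxz, byz, bzz]])
        evals, evecs = np.linalg.eigh(bt)  # ascending
        b = float(np.sum(evals))
        scale = max(abs(b), 1e-12)
        gap_low = abs(evals[1] - evals[0])  # axis = largest eigenvalue
        gap_high = abs(evals[2] - evals[1])  # axis = smallest eigenvalue
        if min(gap_low, gap_high) > axisym_tol * scale:
            raise ValueError(
                f"b-tensor in row {row_index} is not axisymmetric within "
                f"tolerance {axisym_tol}"
            )
        if gap_low <= gap_high:  # two small equal eigenvalues: prolate
            axis = evecs[:, 2]
            lam_axial, lam_radial = evals[2], 0.5 * (evals[0] + evals[1])
        else:  # oblate
            axis = evecs[:, 0]
            lam_axial, lam_radial = evals[0], 0.5 * (evals[1] + evals[2])
        if b > axisym_tol:
            b_delta = (lam_axial - lam_radial) / b
        else:
            b_delta = 0.0
        theta, phi = cartesian_to_spherical(axis)
        b_out.append(b)
        bd_out.append(float(np.clip(b_delta, -0.5, 1.0)))
        th_out.append(float(theta))
        ph_out.append(float(phi))
    return AcquisitionScheme(b_out, bd_out, th_out, ph_out, tr, te)


# -- volumes -----------------------------------------------------------

def write_signal_volume(data: np.ndarray, path, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_dataset(signal_path, acquisition_path, mask_path=None):
    """Load a 4D signal volume, its acquisition table and an optional mask.

    Returns ``(data, affine, mask, scheme)``.  The 4th dimension of the
    volume must match the acquisition row count.
    """
    img = nib.load(str(signal_path))
    data = np.asarray(img.dataobj, dtype=float)
    scheme = read_acquisition_table(acquisition_path)
    if data.ndim != 4:
        raise ValueError("signal volume must be 4D (x, y, z, measurement)")
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"signal has {data.shape[3]} measurements but the acquisition "
            f"table lists {len(scheme)}"
        )
    if mask_path is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    else:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match the signal volume")
    return data, img.affine, mask, scheme


# -- component ensembles ----------------------------------------------

def ensemble_to_frame(ensemble: VoxelEnsemble, voxel=None) -> pd.DataFrame:
    """Tidy table of an ensemble: one row per (bootstrap, component)."""
    frames = []
    for sol in ensemble:
        df = sol.components.to_frame()
        df.insert(0, "nb", sol.bootstrap_index)
        df["residual"] = sol.residual
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["nb", *ComponentSet._FIELDS, "residual"]
    )
    if voxel is not None:
        for axis, value in zip("kji", voxel[::-1]):
            out.insert(0, axis, value)
    return out


def frame_to_ensemble(df: pd.DataFrame, n_bootstrap=None) -> VoxelEnsemble:
    solutions = []
    indices = sorted(df["nb"].unique()) if len(df) else []
    if n_bootstrap is not None:
        indices = range(n_bootstrap)
    for nb in indices:
        sub = df[df["nb"] == nb]
        comps = ComponentSet.from_frame(sub) if len(sub) else ComponentSet.empty()
        residual = float(sub["residual"].iloc[0]) if len(sub) else np.inf
        solutions.append(BootstrapSolution(comps, residual, int(nb)))
    return VoxelEnsemble(solutions)


def write_ensembles(ensembles: dict, path) -> None:
    """All voxel ensembles in one CSV with voxel index columns i, j, k."""
    frames = [
        ensemble_to_frame(ens, voxel=idx) for idx, ens in sorted(ensembles.items())
    ]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    table.to_csv(path, index=False, float_format="%.17g")


def read_ensembles(path) -> dict:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for idx, sub in df.groupby(["i", "j", "k"]):
        out[tuple(int(v) for v in idx)] = frame_to_ensemble(sub)
    return out


def write_maps(maps: dict, out_dir, affine=None) -> list:
    """One NIfTI per descriptor map; '/' in names becomes '_'."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, volume in maps.items():
        fname = out_dir / (name.replace("/", "_").replace("[", "").replace("]", "")
                           .replace(",", "_") + ".nii.gz")
        write_signal_volume(volume, fname, affine)
        written.append(fname)
    return written


def write_provenance(path, config=None, seed=None, extra=None) -> None:
    """Record what produced an output directory: config, seed, versions."""
    import fibert1

    payload = {
        "package": "fibert1",
        "version": getattr(fibert1, "__version__", "unknown"),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": asdict(config) if config is not None else None,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
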