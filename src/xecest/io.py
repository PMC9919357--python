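"""File interfaces: z-spectrum CSV, parameter JSON, scan sets, site YAML.

Conventions: z-spectrum files are CSV with columns offset_ppm,
intensity and optional sigma, with a JSON sidecar for acquisition
metadata; model/fit parameters are JSON with widths reported as a/pi
in Hz; contact-site clusters are YAML mapping site name to residues.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from xecest.contact_analysis import ContactTable, SiteCluster
from xecest.spectra_prep import Scan1D, ZSpectrum
from xecest.zspec_model import ZSpecModelParams, hz_to_ppm

__all__ = [
    "read_zspectrum",
    "write_zspectrum",
    "read_model_params",
    "write_model_params",
    "write_fit_result",
    "read_scan_set",
    "write_scan_set",
    "load_site_clusters",
    "packaged_site_clusters",
    "write_contact_report",
    "write_trajectory_csv",
    "read_trajectory_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_zspectrum(z: ZSpectrum, path: str | Path) -> None:
    path = Path(path)
    cols = {"offset_ppm": z.offsets, "intensity": z.intensities}
    if z.sigma is not None:
        cols["sigma"] = z.sigma
    pd.DataFrame(cols).to_csv(path, index=False)
    if z.metadata:
        _sidecar(path).write_text(json.dumps(z.metadata, indent=2, default=float))


def read_zspectrum(path: str | Path) -> ZSpectrum:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return ZSpectrum(
        offsets=df["offset_ppm"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        sigma=df["sigma"].to_numpy() if "sigma" in df else None,
        metadata=meta,
    )


def write_model_params(params: ZSpecModelParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


def read_model_params(path: str | Path) -> ZSpecModelParams:
    return ZSpecModelParams.from_dict(json.loads(Path(path).read_text()))


def write_fit_result(fit, path: str | Path, extra: dict | None = None) -> None:
    """Write a fit as JSON mirroring the published parameter-table
    layout (position ppm, amplitude B, width a/pi Hz, each with
    standard error)."""
    doc = fit.to_dict()
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=float))


def write_scan_set(scans: list[Scan1D], outdir: str | Path,
                   ref_free_xe_ppm: float = 196.0, f_obs: float = 83.0e6) -> Path:
    """One CSV (ppm, amplitude) per scan plus a manifest CSV keyed by
    the irradiation offset in Hz relative to the free-xenon line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, scan in enumerate(scans):
        fname = f"scan_{i:03d}.csv"
        pd.DataFrame({"ppm": scan.axis, "amplitude": scan.amplitude}).to_csv(
            outdir / fname, index=False
        )
        off_hz = (scan.irradiation_offset - ref_free_xe_ppm) * f_obs * 1e-6
        rows.append({"filename": fname, "irradiation_offset_hz_relative_to_free_xe": off_hz})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_scan_set(manifest: str | Path, ref_free_xe_ppm: float = 196.0,
                  f_obs: float = 83.0e6) -> list[Scan1D]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    scans = []
    for _, row in df.iterrows():
        sdf = pd.read_csv(manifest.parent / row["filename"])
        off_ppm = ref_free_xe_ppm + float(
            hz_to_ppm(row["irradiation_offset_hz_relative_to_free_xe"], f_obs)
        )
        scans.append(
            Scan1D(
                axis=sdf["ppm"].to_numpy(),
                amplitude=sdf["amplitude"].to_numpy(),
                irradiation_offset=off_ppm,
            )
        )
    return scans


def _clusters_from_mapping(mapping: dict) -> list[SiteCluster]:
    return [SiteCluster(name=k, residues=tuple(v)) for k, v in mapping.items()]


def load_site_clusters(path: str | Path, system: str | None = None) -> list[SiteCluster]:
    """Load site clusters from YAML: either a flat mapping
    {site: [residues]} or a two-level {system: {site: [residues]}}."""
    doc = yaml.safe_load(Path(path).read_text())
    if system is not None:
        doc = doc[system]
    if doc and isinstance(next(iter(doc.values())), dict):
        raise ValueError("multi-system site file: pass system='apo' or 'npy'")
    return _clusters_from_mapping(doc)


def packaged_site_clusters(system: str = "apo") -> list[SiteCluster]:
    """The default contact-site definitions shipped with the package."""
    text = resources.files("xecest.data").joinpath("table2_sites.yaml").read_text()
    return _clusters_from_mapping(yaml.safe_load(text)[system])


def write_contact_report(
    table: ContactTable,
    outdir: str | Path,
    clusters: list[SiteCluster] | None = None,
) -> None:
    """ContactTable as CSV plus a JSON summary of category and site
    probabilities."""
    from xecest.contact_analysis import site_contact_probability

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_dataframe().to_csv(outdir / "contacts.csv", index=False)
    summary = {
        "n_frames": table.n_frames,
        "cutoff_angstrom": table.cutoff,
        "equilibration_discard_ns": table.equilibration_discard_ns,
        "category_probabilities": table.category_probabilities(),
    }
    if clusters:
        summary["site_probabilities"] = {
            c.name: site_contact_probability(table, c) for c in clusters
        }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))


def write_trajectory_csv(traj, outdir: str | Path) -> None:
    """Plain-text trajectory: atoms.csv (labels) + frames.csv (coordinates)."""
    from xecest.contact_analysis import Trajectory  # noqa: F401  (type only)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "resname": traj.resnames,
            "resid": traj.resids,
            "name": traj.names,
            "heavy": np.asarray(traj.heavy, dtype=int),
            "category": traj.category,
        }
    ).to_csv(outdir / "atoms.csv", index=False)
    n_frames, n_atoms, _ = traj.coords.shape
    frames = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n_atoms),
            "time_ns": np.repeat(traj.times_ns, n_atoms),
            "atom": np.tile(np.arange(n_atoms), n_frames),
            "x": traj.coords[:, :, 0].ravel(),
            "y": traj.coords[:, :, 1].ravel(),
            "z": traj.coords[:, :, 2].ravel(),
        }
    )
    frames.to_csv(outdir / "frames.csv", index=False)


def read_trajectory_csv(outdir: str | Path):
    """Inverse of :func:`write_trajectory_csv`."""
    from xecest.contact_analysis import Trajectory

    outdir = Path(outdir)
    atoms = pd.read_csv(outdir / "atoms.csv")
    frames = pd.read_csv(outdir / "frames.csv")
    n_atoms = len(atoms)
    n_frames = frames["frame"].nunique()
    coords = frames[["x", "y", "z"]].to_numpy().reshape(n_frames, n_atoms, 3)
    times = frames["time_ns"].to_numpy().reshape(n_frames, n_atoms)[:, 0]
    return Trajectory(
        coords=coords,
        times_ns=times,
        resids=atoms["resid"].to_numpy(),
        resnames=atoms["resname"].to_numpy().astype(str),
        names=atoms["name"].to_numpy().astype(str),
        heavy=atoms["heavy"].to_numpy().astype(bool),
        category=atoms["category"].to_numpy().astype(str),
    )
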