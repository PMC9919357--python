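"""Internal order parameters and RMSD from aligned trajectories.

Overall receptor reorientation is removed by rigid-body superposition
of each frame onto a reference structure (Kabsch least squares over the
receptor C-alpha atoms).  The per-residue order parameter is then the
generalized S^2 of the C-alpha-H bond vector, computed from the
time-averaged second moments of the aligned unit vectors:

    S^2 = (3/2) * sum_{a,b in xyz} <u_a u_b>^2 - 1/2

which is 1 for a rigid vector and 0 in the isotropic limit.  The
autocorrelation (2nd Legendre polynomial) route is deliberately not
used: it requires overall rotation to average out, which does not hold
for a membrane-embedded receptor on the relevant time scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from xecest.contact_analysis import Trajectory, residue_label

__all__ = [
    "SuperpositionResult",
    "OrderParamResult",
    "superpose",
    "order_parameter",
    "per_residue_order",
    "rmsd_series",
    "reconstruct_ca_h_direction",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid-body superposition: x_fit = (x_mobile - centroid_m) @ R.T + centroid_ref."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be a proper orthogonal 3x3 matrix")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class OrderParamResult:
    """Per-residue S^2 values keyed by (segment category, residue label),
    with arithmetic-mean region averages."""

    values: dict
    receptor_average: float
    ligand_average: float | None


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid-body superposition (Kabsch algorithm).

    Returns the proper rotation and translation minimizing the RMSD of
    mobile onto reference, plus the post-fit RMSD.  Requires at least 3
    non-collinear points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("mobile and reference must be matching (n>=3, 3) arrays")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-10) < 2:
        raise ValueError("selection is collinear or degenerate; superposition is ill-posed")
    H = P0.T @ Q0
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = P0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q0) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=cq - R @ cp, rmsd=rmsd)


def order_parameter(unit_vectors: np.ndarray) -> float:
    """Generalized S^2 from unit bond vectors over frames.

    unit_vectors : (n_frames, 3), normalized.  The value is clipped to
    [0, 1]; a clip larger than 1e-6 triggers a warning.
    """
    u = np.asarray(unit_vectors, dtype=float)
    if u.ndim != 2 or u.shape[1] != 3 or u.shape[0] < 2:
        raise ValueError("need (n_frames >= 2, 3) unit vectors")
    norms = np.linalg.norm(u, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length bond vector")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        u = u / norms[:, None]
    # second-moment tensor <u_a u_b>
    M = u.T @ u / u.shape[0]
    s2 = 1.5 * float(np.sum(M * M)) - 0.5
    if s2 < -1e-6 or s2 > 1.0 + 1e-6:
        warnings.warn(f"S^2 = {s2:.3g} outside [0, 1]; clipping", stacklevel=2)
    return float(np.clip(s2, 0.0, 1.0))


def reconstruct_ca_h_direction(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                               cb: np.ndarray | None = None) -> np.ndarray:
    """Effective C-alpha-H direction from backbone geometry.

    With a tetrahedral C-alpha the H direction opposes the sum of the
    unit vectors toward N, C and (when present) C-beta; without C-beta
    the in-plane bisector construction is used.  Intended for
    topologies lacking explicit hydrogens.
    """
    vn = (n - ca) / np.linalg.norm(n - ca)
    vc = (c - ca) / np.linalg.norm(c - ca)
    total = vn + vc
    if cb is not None:
        total = total + (cb - ca) / np.linalg.norm(cb - ca)
    h = -total
    norm = np.linalg.norm(h)
    if norm == 0:
        raise ValueError("degenerate backbone geometry")
    return h / norm


def _alignment_selection(traj: Trajectory) -> np.ndarray:
    """Receptor C-alpha atoms: the alignment never includes ligand or cage."""
    cat = np.asarray(traj.category)
    names = np.asarray(traj.names)
    sel = np.flatnonzero((cat == "receptor") & (names == "CA"))
    if sel.size < 3:
        raise ValueError("need at least 3 receptor CA atoms for alignment")
    return sel


def _aligned_coords(traj: Trajectory, reference_frame: int) -> np.ndarray:
    """All-atom coordinates after per-frame superposition on receptor CA."""
    sel = _alignment_selection(traj)
    ref = traj.coords[reference_frame, sel]
    out = np.empty_like(traj.coords)
    for i in range(traj.n_frames):
        fit = superpose(traj.coords[i, sel], ref)
        out[i] = fit.apply(traj.coords[i])
    return out


def per_residue_order(
    traj: Trajectory,
    reference_frame: int = 0,
    reconstruct_h: bool = False,
) -> OrderParamResult:
    """Per-residue C-alpha-H order parameters after global alignment.

    Frames are superposed on the receptor C-alpha atoms of the
    reference frame; S^2 is then computed per residue from the aligned
    CA-HA unit vectors.  Residues lacking a CA-HA pair are skipped with
    a warning (or, with reconstruct_h=True, an effective H direction is
    rebuilt from N/CA/C(/CB) geometry).  Region averages are arithmetic
    means over receptor and ligand residues.
    """
    aligned = _aligned_coords(traj, reference_frame)
    cat = np.asarray(traj.category)
    names = np.asarray(traj.names)
    resids = np.asarray(traj.resids)
    resnames = np.asarray(traj.resnames)
    values: dict = {}
    skipped = []
    for segment in ("receptor", "ligand"):
        seg_atoms = np.flatnonzero(cat == segment)
        if seg_atoms.size == 0:
            continue
        for rid in np.unique(resids[seg_atoms]):
            atoms = seg_atoms[resids[seg_atoms] == rid]
            label = residue_label(str(resnames[atoms[0]]), int(rid))
            ca = atoms[names[atoms] == "CA"]
            ha = atoms[np.isin(names[atoms], ("HA", "HA1", "HA2"))]
            if ca.size == 0 or (ha.size == 0 and not reconstruct_h):
                skipped.append(label)
                continue
            if ha.size:
                vec = aligned[:, ha[0]] - aligned[:, ca[0]]
            else:
                n_at = atoms[names[atoms] == "N"]
                c_at = atoms[names[atoms] == "C"]
                cb_at = atoms[names[atoms] == "CB"]
                if n_at.size == 0 or c_at.size == 0:
                    skipped.append(label)
                    continue
                vec = np.stack([
                    reconstruct_ca_h_direction(
                        aligned[i, n_at[0]],
                        aligned[i, ca[0]],
                        aligned[i, c_at[0]],
                        aligned[i, cb_at[0]] if cb_at.size else None,
                    )
                    for i in range(traj.n_frames)
                ])
            norms = np.linalg.norm(vec, axis=1)
            values[(segment, label)] = order_parameter(vec / norms[:, None])
    if skipped:
        warnings.warn(
            f"{len(skipped)} residues lack a CA-H pair and were skipped: "
            f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}",
            stacklevel=2,
        )
    if not values:
        raise ValueError("no residue provided a CA-H bond vector")
    rec = [v for (seg, _), v in values.items() if seg == "receptor"]
    lig = [v for (seg, _), v in values.items() if seg == "ligand"]
    return OrderParamResult(
        values=values,
        receptor_average=float(np.mean(rec)) if rec else float("nan"),
        ligand_average=float(np.mean(lig)) if lig else None,
    )


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: np.ndarray | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) over a selection.

    With fit=True (default) each frame is first superposed onto the
    reference over the selection; fit=False computes the plain
    coordinate RMSD.  selection defaults to the receptor C-alpha atoms
    (also the atoms the superposition itself uses).
    """
    sel = _alignment_selection(traj) if selection is None else np.asarray(selection)
    ref = traj.coords[reference_frame, sel]
    if fit:
        return np.array(
            [superpose(traj.coords[i, sel], ref).rmsd for i in range(traj.n_frames)]
        )
    diff = traj.coords[:, sel] - ref[None]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
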