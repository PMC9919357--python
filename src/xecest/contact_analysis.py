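"""Xenon contact statistics from MD trajectories.

A single xenon atom (inside its cryptophane cage) explores the
receptor/membrane system; a residue or lipid molecule is *in contact*
in a frame when the xenon sits within a cutoff distance (default 8.5 A)
of any of its heavy atoms.  Frames are categorized by what the xenon
touches — "just lipid", "just protein" (receptor and/or ligand),
"lipid and protein", or "no contacts" — and named residue clusters
(contact sites) are scored by the mean contact probability of their
three most-contacted residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "SEGMENT_CATEGORIES",
    "Trajectory",
    "SiteCluster",
    "ContactTable",
    "residue_label",
    "contacts_in_frame",
    "build_contact_table",
    "site_contact_probability",
    "normalize_counts_for_projection",
    "load_trajectory",
]

#: Per-frame environment categories (a partition of retained frames).
CATEGORIES = ("just lipid", "just protein", "lipid and protein", "no contacts")

SEGMENT_CATEGORIES = ("receptor", "ligand", "lipid", "cage", "xenon", "solvent")

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "HSD": "H",
    "ILE": "I", "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F",
    "PRO": "P", "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y",
    "VAL": "V",
}


def residue_label(resname: str, resid: int) -> str:
    """Compact residue identifier: one-letter code + number for amino
    acids (L40), residue name + number otherwise (DMPC7)."""
    return _ONE_LETTER.get(resname.upper(), resname) + str(resid)


@dataclass(frozen=True)
class Trajectory:
    """Labelled coordinates over frames.

    coords : (n_frames, n_atoms, 3) positions in Angstrom.
    times_ns : strictly increasing frame times.
    resids / resnames / names : per-atom residue number, residue name,
        atom name.
    heavy : per-atom flag, True for non-hydrogen atoms.
    category : per-atom segment category, one of
        receptor | ligand | lipid | cage | xenon | solvent.
    box : optional orthorhombic box lengths (3,) in Angstrom for
        minimum-image distances; None means non-periodic.
    """

    coords: np.ndarray
    times_ns: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    names: np.ndarray
    heavy: np.ndarray
    category: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        times = np.asarray(self.times_ns, dtype=float)
        if times.shape != (coords.shape[0],) or np.any(np.diff(times) <= 0):
            raise ValueError("times_ns must be strictly increasing, one per frame")
        n_atoms = coords.shape[1]
        for attr in ("resids", "resnames", "names", "heavy", "category"):
            if np.asarray(getattr(self, attr)).shape != (n_atoms,):
                raise ValueError(f"{attr} must have one entry per atom")
        cat = np.asarray(self.category)
        unknown = set(cat) - set(SEGMENT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown segment categories: {sorted(unknown)}")
        if int(np.sum(cat == "xenon")) != 1:
            raise ValueError("trajectory must contain exactly one xenon atom")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "times_ns", times)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def xenon_index(self) -> int:
        return int(np.flatnonzero(np.asarray(self.category) == "xenon")[0])


@dataclass(frozen=True)
class SiteCluster:
    """Named contact site: a small group of residues (cluster)."""

    name: str
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"cluster {self.name} has no residues")
        object.__setattr__(self, "residues", tuple(self.residues))


@dataclass(frozen=True)
class ContactTable:
    """Per-residue xenon contact counts over retained frames.

    counts maps (segment category, residue label) -> number of frames
    in contact; frame_categories holds one environment category per
    retained frame.
    """

    counts: dict
    frame_categories: tuple[str, ...]
    n_frames: int
    cutoff: float
    equilibration_discard_ns: float

    def __post_init__(self) -> None:
        if len(self.frame_categories) != self.n_frames:
            raise ValueError("one category per retained frame required")
        bad = set(self.frame_categories) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown frame categories: {sorted(bad)}")
        if any(c > self.n_frames for c in self.counts.values()):
            raise ValueError("contact count exceeds number of frames")

    def category_probabilities(self) -> dict:
        """Fraction of retained frames in each environment category."""
        cats = np.asarray(self.frame_categories)
        return {c: float(np.mean(cats == c)) for c in CATEGORIES}

    def residue_probability(self, label: str) -> float:
        """Contact probability of one residue (searched across protein
        segments)."""
        for cat in ("receptor", "ligand", "lipid"):
            if (cat, label) in self.counts:
                return self.counts[(cat, label)] / self.n_frames
        return 0.0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "category": cat,
                "residue": label,
                "count": cnt,
                "probability": cnt / self.n_frames,
            }
            for (cat, label), cnt in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["category", "residue", "count", "probability"])


def _frame_distances(traj: Trajectory, i: int, idx: np.ndarray) -> np.ndarray:
    """Distances from the xenon to the selected atoms in frame i,
    minimum-image when a box is present."""
    xe = traj.coords[i, traj.xenon_index]
    d = traj.coords[i, idx] - xe
    if traj.box is not None:
        d -= traj.box * np.round(d / traj.box)
    return np.linalg.norm(d, axis=1)


def _contact_atom_index(traj: Trajectory) -> np.ndarray:
    """Heavy atoms eligible for contacts: receptor, ligand and lipid.

    Solvent is ignored by definition; the cage (and the xenon itself)
    is excluded because the xenon permanently resides inside it.
    """
    cat = np.asarray(traj.category)
    eligible = np.isin(cat, ("receptor", "ligand", "lipid"))
    return np.flatnonzero(eligible & np.asarray(traj.heavy, dtype=bool))


def contacts_in_frame(traj: Trajectory, frame: int, cutoff: float = 8.5) -> set:
    """Residues/lipid molecules in contact with the xenon in one frame.

    Returns a set of (segment category, residue label) pairs; a residue
    is in contact iff the minimum xenon-to-heavy-atom distance is below
    the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    idx = _contact_atom_index(traj)
    if idx.size == 0:
        return set()
    dist = _frame_distances(traj, frame, idx)
    hit = idx[dist < cutoff]
    return {
        (str(traj.category[j]), residue_label(str(traj.resnames[j]), int(traj.resids[j])))
        for j in hit
    }


def _categorize(contacts: set) -> str:
    has_lipid = any(cat == "lipid" for cat, _ in contacts)
    has_protein = any(cat in ("receptor", "ligand") for cat, _ in contacts)
    if has_lipid and has_protein:
        return "lipid and protein"
    if has_lipid:
        return "just lipid"
    if has_protein:
        return "just protein"
    return "no contacts"


def build_contact_table(
    traj: Trajectory, cutoff: float = 8.5, discard_ns: float = 100.0
) -> ContactTable:
    """Count contacts and categorize every frame after equilibration.

    Frames with time < discard_ns are treated as equilibration and
    dropped.  Each retained frame contributes one contact instance per
    residue in contact and exactly one environment category.
    """
    keep = np.flatnonzero(traj.times_ns >= discard_ns)
    if keep.size == 0:
        raise ValueError(
            f"all {traj.n_frames} frames fall inside the {discard_ns} ns "
            "equilibration discard"
        )
    if traj.box is None:
        warnings.warn(
            "no box vectors: using plain Euclidean distances (no minimum image)",
            stacklevel=2,
        )
    counts: dict = {}
    frame_cats = []
    for i in keep:
        contacts = contacts_in_frame(traj, int(i), cutoff)
        frame_cats.append(_categorize(contacts))
        for key in contacts:
            counts[key] = counts.get(key, 0) + 1
    return ContactTable(
        counts=counts,
        frame_categories=tuple(frame_cats),
        n_frames=int(keep.size),
        cutoff=float(cutoff),
        equilibration_discard_ns=float(discard_ns),
    )


def site_contact_probability(table: ContactTable, cluster: SiteCluster) -> float:
    """Mean contact probability of the cluster's three most-contacted
    residues (all of them when the cluster lists exactly three).

    Residues named in the cluster but absent from the table count as
    probability zero.  Ties in the top-3 ranking are broken by the
    residue's position in the cluster list (stable sort), which follows
    the residue numbering the cluster was written with.
    """
    probs = [table.residue_probability(label) for label in cluster.residues]
    if len(probs) < 3:
        warnings.warn(
            f"cluster {cluster.name} lists {len(probs)} residues; averaging "
            "over the available ones",
            stacklevel=2,
        )
        top = probs
    else:
        top = sorted(probs, reverse=True)[:3]
    return float(np.mean(top))


def normalize_counts_for_projection(table: ContactTable) -> dict:
    """Per-residue counts scaled to [0, 1] by the per-system maximum.

    This is the normalization used to color contact instances on a
    structure surface; scales are per system and therefore not
    comparable across systems.
    """
    if not table.counts or max(table.counts.values()) == 0:
        raise ValueError("no nonzero contact counts to normalize")
    peak = max(table.counts.values())
    return {key: cnt / peak for key, cnt in table.counts.items()}


def load_trajectory(
    topology: str,
    trajectory: str | None = None,
    category_map: dict | None = None,
    time_unit_ns: float = 1e-3,
) -> Trajectory:
    """Read a topology (PDB) and coordinate file (DCD/XTC/...) into a
    labelled :class:`Trajectory` via MDAnalysis.

    category_map maps residue names to segment categories; residue
    names not listed default to solvent for common water/ion names and
    receptor otherwise.  MDAnalysis reports times in ps, converted here
    with ``time_unit_ns``.
    """
    import MDAnalysis as mda

    category_map = dict(category_map or {})
    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    atoms = u.atoms
    resnames = atoms.resnames.astype(str)
    default_solvent = {"HOH", "TIP3", "SOL", "WAT", "NA", "CL", "SOD", "CLA", "POT"}

    def _category(rn: str) -> str:
        if rn in category_map:
            return category_map[rn]
        if rn.upper() in ("XE", "XEN"):
            return "xenon"
        if rn.upper() in default_solvent:
            return "solvent"
        return "receptor"

    names = atoms.names.astype(str)
    heavy = np.array([not n.startswith(("H", "1H", "2H", "3H")) for n in names])
    category = np.array([_category(rn) for rn in resnames])
    coords, times = [], []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float).copy())
        times.append(float(ts.time) * time_unit_ns)  # ps -> ns by default
    times = np.asarray(times)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(times.size, dtype=float)  # fall back to frame index
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = u.dimensions[:3].astype(float)
    return Trajectory(
        coords=np.asarray(coords),
        times_ns=times,
        resids=atoms.resids.astype(int),
        resnames=resnames,
        names=names,
        heavy=heavy,
        category=category,
        box=box,
    )
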