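"""Ground-truth generators for every pipeline input.

No raw spectra or trajectories are distributed with this package, so
each analysis stage is exercised on synthetic data with known truth:

* z-spectra evaluated from the published fit-parameter sets on the
  experimental acquisition grid, plus Gaussian noise;
* per-scan direct-detection spectra whose free-xenon peak area encodes
  the z-value, for the integration stage;
* toy trajectories where the xenon hops between contact sites as a
  Markov chain with a known stationary distribution;
* wobble-in-cone bond-vector trajectories with closed-form order
  parameters  S = cos(theta) (1 + cos(theta)) / 2,  S^2 tabulated.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from xecest.contact_analysis import Trajectory
from xecest.spectra_prep import Scan1D, ZSpectrum
from xecest.zspec_model import (
    AcquisitionParams,
    Resonance,
    ZSpecModelParams,
    evaluate_zspectrum,
)

__all__ = [
    "DEFAULT_NOISE_SIGMA",
    "Table1Preset",
    "HopState",
    "HopModel",
    "table1_presets",
    "gen_zspectrum",
    "gen_scan_set",
    "default_hop_model",
    "stationary_distribution",
    "gen_hop_trajectory",
    "cone_order_parameter",
    "gen_cone_trajectory",
]

#: Default Gaussian noise on synthetic z-spectra, as a fraction of the
#: baseline A.  The published spectra show point scatter of about 1%.
DEFAULT_NOISE_SIGMA = 0.01


@dataclass(frozen=True)
class Table1Preset:
    """A published fit-parameter set (positions ppm, amplitudes B,
    widths a/pi in Hz), optionally with direct-detection line positions
    and widths for the free-host control."""

    label: str
    params: ZSpecModelParams | None
    direct_lines: tuple = ()


def _preset(label: str, rows: list[tuple[float, float, float]]) -> Table1Preset:
    return Table1Preset(
        label=label,
        params=ZSpecModelParams(
            A=1.0,
            resonances=tuple(Resonance.from_width_hz(b, B, w) for b, B, w in rows),
        ),
    )


def table1_presets() -> dict[str, Table1Preset]:
    """The published parameter sets, central values, baseline A = 1.

    apo: the receptor-cage conjugate alone (5 resonances);
    npy: the conjugate in complex with neuropeptide Y (6 resonances);
    control_construct_bicelles: the free cage-dye construct in a bicelle
    suspension (1 resonance);
    control_free_cra: the carboxylated free cage, characterized in
    direct detection only (two lines: lipid and aqueous environment).
    """
    return {
        "apo": _preset(
            "apo",
            [
                (103.3, 0.069, 820.0),
                (91.9, 0.077, 947.0),
                (77.5, 2.300, 573.0),
                (67.2, 0.163, 242.0),
                (58.8, 0.092, 1570.0),
            ],
        ),
        "npy": _preset(
            "npy",
            [
                (104.9, 0.089, 322.0),
                (92.4, 0.136, 704.0),
                (77.5, 2.120, 618.0),
                (70.0, 0.181, 466.0),
                (63.0, 0.182, 785.0),
                (49.5, 0.109, 417.0),
            ],
        ),
        "control_construct_bicelles": _preset(
            "control_construct_bicelles", [(77.9, 2.206, 497.0)]
        ),
        "control_free_cra": Table1Preset(
            label="control_free_cra",
            params=None,
            direct_lines=((77.3, 320.0), (63.7, 24.0)),
        ),
    }


def _resolve_params(preset) -> ZSpecModelParams:
    if isinstance(preset, Table1Preset):
        if preset.params is None:
            raise ValueError(f"preset {preset.label!r} has no z-spectrum model")
        return preset.params
    if isinstance(preset, ZSpecModelParams):
        return preset
    raise TypeError("expected a Table1Preset or ZSpecModelParams")


def gen_zspectrum(
    preset,
    acq: AcquisitionParams | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ZSpectrum:
    """Forward-model z-spectrum on the acquisition grid plus iid noise.

    noise_sigma is the Gaussian standard deviation in intensity units
    (the baseline is A); 0 gives the exact forward model.  The seed
    fully determines the output.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    acq = acq or AcquisitionParams()
    params = _resolve_params(preset)
    offsets = acq.offsets_ppm()
    if offsets.size == 0:
        raise ValueError("empty acquisition grid")
    clean = evaluate_zspectrum(params, offsets, acq.f_obs)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape) if noise_sigma else clean
    sigma = np.full_like(clean, noise_sigma) if noise_sigma else None
    label = preset.label if isinstance(preset, Table1Preset) else None
    return ZSpectrum(
        offsets=offsets,
        intensities=noisy,
        sigma=sigma,
        metadata={
            "f_obs": acq.f_obs,
            "seed": seed,
            "noise_sigma": noise_sigma,
            "preset": label,
        },
    )


def gen_scan_set(
    preset,
    acq: AcquisitionParams | None = None,
    peak_fwhm_ppm: float = 0.5,
    axis_halfwidth_ppm: float = 16.0,
    axis_step_ppm: float = 0.05,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[Scan1D]:
    """Per-offset direct-detection spectra for the integration stage.

    Each scan holds one Lorentzian free-xenon peak at the reference
    position whose *area* equals the forward-model z-value at that
    scan's irradiation offset (saturation depletes the pool, not the
    lineshape).  An empty resonance list gives constant peak areas.
    """
    acq = acq or AcquisitionParams()
    params = _resolve_params(preset)
    offsets = acq.offsets_ppm()
    z = evaluate_zspectrum(params, offsets, acq.f_obs)
    axis = np.arange(
        acq.ref_free_xe_ppm - axis_halfwidth_ppm,
        acq.ref_free_xe_ppm + axis_halfwidth_ppm + axis_step_ppm / 2,
        axis_step_ppm,
    )
    gamma = peak_fwhm_ppm / 2.0  # Lorentzian HWHM
    shape = (gamma / math.pi) / ((axis - acq.ref_free_xe_ppm) ** 2 + gamma**2)
    rng = np.random.default_rng(seed)
    scans = []
    for off, area in zip(offsets, z):
        amp = area * shape
        if noise_sigma:
            amp = amp + rng.normal(0.0, noise_sigma, size=amp.shape)
        scans.append(Scan1D(axis=axis, amplitude=amp, irradiation_offset=float(off)))
    return scans


# --------------------------------------------------------------------------
# Markov site-hopping trajectories (contact-statistics ground truth)


@dataclass(frozen=True)
class HopState:
    """One xenon site: a name, the frame category it produces by
    construction, and the xenon position (Angstrom) when occupied."""

    name: str
    category: str
    position: tuple[float, float, float]


@dataclass(frozen=True)
class HopModel:
    """Markov chain over xenon sites with a row-stochastic transition
    matrix; the chain must be irreducible so the stationary
    distribution is unique."""

    states: tuple[HopState, ...]
    transition: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        P = np.asarray(self.transition, dtype=float)
        k = len(self.states)
        if P.shape != (k, k):
            raise ValueError("transition matrix shape must match the state count")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        reach = np.linalg.matrix_power(np.eye(k) + (P > 0), k) > 0
        if not reach.all():
            raise ValueError("transition chain is reducible")
        object.__setattr__(self, "transition", P)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix (left eigenvector of
    eigenvalue 1, normalized to sum 1)."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# Toy topology used by the hop generator.  Distances are laid out so
# each state's contact set is unambiguous at the 8.5 A cutoff: the
# protein site and the lipid site are ~60 A apart; one lipid molecule
# sits 12 A from the protein so the interface position touches both.
_HOP_ATOMS = [
    # (resname, resid, name, heavy, category, x, y, z)
    ("LEU", 40, "CA", True, "receptor", 0.0, 0.0, 0.0),
    ("ILE", 41, "CA", True, "receptor", 3.8, 0.0, 0.0),
    ("LYS", 45, "CA", True, "receptor", 0.0, -3.8, 0.0),
    ("DMPC", 1, "C2", True, "lipid", 60.0, 0.0, 0.0),
    ("DMPC", 2, "C2", True, "lipid", 0.0, 12.0, 0.0),
    ("HOH", 900, "OH2", True, "solvent", 200.0, 200.0, 196.0),
    ("XE", 999, "XE", True, "xenon", 200.0, 200.0, 200.0),
]


def default_hop_model() -> HopModel:
    """Three-site chain: a lipid pocket, a protein site and bulk water."""
    return HopModel(
        states=(
            HopState("lipid_pocket", "just lipid", (60.0, 0.0, 4.0)),
            HopState("protein_site", "just protein", (0.0, 0.0, 4.0)),
            HopState("bulk", "no contacts", (200.0, 200.0, 200.0)),
        ),
        transition=np.array(
            [[0.8, 0.1, 0.1], [0.2, 0.7, 0.1], [0.3, 0.2, 0.5]]
        ),
    )


def interface_hop_model() -> HopModel:
    """Four-site chain adding a simultaneous lipid-and-protein contact."""
    return HopModel(
        states=(
            HopState("lipid_pocket", "just lipid", (60.0, 0.0, 4.0)),
            HopState("protein_site", "just protein", (0.0, 0.0, 4.0)),
            HopState("interface", "lipid and protein", (0.0, 6.0, 0.0)),
            HopState("bulk", "no contacts", (200.0, 200.0, 200.0)),
        ),
        transition=np.array(
            [
                [0.7, 0.1, 0.1, 0.1],
                [0.1, 0.7, 0.1, 0.1],
                [0.1, 0.1, 0.7, 0.1],
                [0.2, 0.2, 0.1, 0.5],
            ]
        ),
    )


def gen_hop_trajectory(
    model: HopModel | None = None,
    n_frames: int = 2000,
    dt_ns: float = 0.1,
    seed: int = 0,
    jitter: float = 0.3,
) -> tuple[Trajectory, dict]:
    """Simulate the site-hopping chain and emit trajectory + truth.

    The xenon is placed at the occupied state's position (plus a small
    uniform jitter that never changes the contact set); all other atoms
    are static.  Truth carries the analytic stationary distribution and
    the implied frame-category probabilities, so downstream tests are
    self-contained.
    """
    model = model or default_hop_model()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(model.states)
    pi = stationary_distribution(model.transition)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(k, p=pi)
    for t in range(1, n_frames):
        states[t] = rng.choice(k, p=model.transition[states[t - 1]])

    base = np.array([[a[5], a[6], a[7]] for a in _HOP_ATOMS])
    xe_row = next(i for i, a in enumerate(_HOP_ATOMS) if a[4] == "xenon")
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    positions = np.array([s.position for s in model.states])
    coords[:, xe_row, :] = positions[states] + rng.uniform(-jitter, jitter, (n_frames, 3))

    traj = Trajectory(
        coords=coords,
        times_ns=dt_ns * (1 + np.arange(n_frames)),
        resids=np.array([a[1] for a in _HOP_ATOMS]),
        resnames=np.array([a[0] for a in _HOP_ATOMS]),
        names=np.array([a[2] for a in _HOP_ATOMS]),
        heavy=np.array([a[3] for a in _HOP_ATOMS]),
        category=np.array([a[4] for a in _HOP_ATOMS]),
    )
    category_probs = {c: 0.0 for c in ("just lipid", "just protein", "lipid and protein", "no contacts")}
    for s, p in zip(model.states, pi):
        category_probs[s.category] += float(p)
    truth = {
        "stationary": {s.name: float(p) for s, p in zip(model.states, pi)},
        "category_probs": category_probs,
        "state_sequence": states,
    }
    return traj, truth


# --------------------------------------------------------------------------
# wobble-in-cone trajectories (order-parameter ground truth)


def cone_order_parameter(angle_deg: float) -> float:
    """Closed-form S^2 for uniform wobble in a cone of semi-angle theta:
    S = cos(theta) (1 + cos(theta)) / 2, returned squared."""
    c = math.cos(math.radians(angle_deg))
    return (c * (1.0 + c) / 2.0) ** 2


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking the z axis onto the given unit axis."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def gen_cone_trajectory(
    angles_deg,
    n_frames: int = 2000,
    seed: int = 0,
    global_rotation: bool = False,
    bond_length: float = 1.09,
) -> Trajectory:
    """Trajectory whose CA-HA vectors wobble uniformly in per-residue cones.

    One glycine-like residue per cone angle, CA atoms fixed on a
    (non-collinear) ring, HA placed along a unit vector drawn uniformly
    over the spherical cap of the residue's cone about a fixed axis.
    With global_rotation=True every frame is additionally rotated
    rigidly by a random rotation, which alignment must remove.  A
    far-away dummy xenon satisfies the trajectory container.
    """
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if np.any(angles <= 0) or np.any(angles > 90):
        raise ValueError("cone semi-angles must lie in (0, 90] degrees")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    n_res = max(angles.size, 3)  # alignment needs >= 3 CA atoms
    angles = np.resize(angles, n_res)
    rng = np.random.default_rng(seed)

    phi = 2 * math.pi * np.arange(n_res) / n_res
    ca = np.column_stack([10 * np.cos(phi), 10 * np.sin(phi), 2.0 * np.arange(n_res)])
    axes = np.column_stack(
        [np.sin(0.7 * np.arange(n_res) + 0.3), np.cos(0.4 * np.arange(n_res)), 1.5 + 0 * phi]
    )
    axes /= np.linalg.norm(axes, axis=1)[:, None]

    resnames, resids, names, heavy, category, base = [], [], [], [], [], []
    for r in range(n_res):
        resnames += ["GLY", "GLY"]
        resids += [r + 1, r + 1]
        names += ["CA", "HA"]
        heavy += [True, False]
        category += ["receptor", "receptor"]
        base += [ca[r], ca[r]]  # HA filled per frame
    resnames.append("XE"); resids.append(999); names.append("XE")
    heavy.append(True); category.append("xenon"); base.append(np.array([500.0, 500.0, 500.0]))
    base = np.asarray(base)

    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    for r in range(n_res):
        cos_t = math.cos(math.radians(angles[r]))
        z = rng.uniform(cos_t, 1.0, n_frames)  # uniform over the spherical cap
        az = rng.uniform(0.0, 2 * math.pi, n_frames)
        s = np.sqrt(1.0 - z**2)
        local = np.column_stack([s * np.cos(az), s * np.sin(az), z])
        u = local @ _rotation_to(axes[r]).T
        coords[:, 2 * r + 1, :] = ca[r] + bond_length * u
    if global_rotation:
        for t in range(n_frames):
            coords[t] = coords[t] @ _random_rotation(rng).T
    return Trajectory(
        coords=coords,
        times_ns=0.1 * (1 + np.arange(n_frames)),
        resids=np.asarray(resids),
        resnames=np.asarray(resnames),
        names=np.asarray(names),
        heavy=np.asarray(heavy),
        category=np.asarray(category),
    )
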