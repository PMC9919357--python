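"""Xenon contact statistics: cutoff rule, frame categories, site scores."""

import numpy as np
import pytest

from xecest.contact_analysis import (
    ContactTable,
    SiteCluster,
    Trajectory,
    build_contact_table,
    contacts_in_frame,
    normalize_counts_for_projection,
    residue_label,
    site_contact_probability,
)
from xecest.synthetic_data import (
    default_hop_model,
    gen_hop_trajectory,
    interface_hop_model,
    stationary_distribution,
)


def toy_trajectory(xe_positions, atoms):
    """Trajectory with static labelled atoms and a moving xenon.

    atoms: list of (resname, resid, name, heavy, category, xyz).
    """
    n_frames = len(xe_positions)
    base = np.array([a[5] for a in atoms] + [[0.0, 0.0, 0.0]])
    coords = np.repeat(base[None], n_frames, axis=0)
    coords[:, -1, :] = np.asarray(xe_positions)
    return Trajectory(
        coords=coords,
        times_ns=1.0 + np.arange(n_frames, dtype=float),
        resids=np.array([a[1] for a in atoms] + [999]),
        resnames=np.array([a[0] for a in atoms] + ["XE"]),
        names=np.array([a[2] for a in atoms] + ["XE"]),
        heavy=np.array([a[3] for a in atoms] + [True]),
        category=np.array([a[4] for a in atoms] + ["xenon"]),
    )


LEU = ("LEU", 40, "CA", True, "receptor", [0.0, 0.0, 0.0])
DMPC = ("DMPC", 1, "C2", True, "lipid", [30.0, 0.0, 0.0])
WATER = ("HOH", 900, "OH2", True, "solvent", [0.0, 0.0, 2.0])


class TestContactsInFrame:
    def test_isolated_xenon_has_no_contacts(self):
        traj = toy_trajectory([[100.0, 100.0, 100.0]], [LEU, DMPC])
        assert contacts_in_frame(traj, 0) == set()

    def test_cutoff_boundary(self):
        near = toy_trajectory([[8.4, 0.0, 0.0]], [LEU])
        far = toy_trajectory([[8.6, 0.0, 0.0]], [LEU])
        assert contacts_in_frame(near, 0) == {("receptor", "L40")}
        assert contacts_in_frame(far, 0) == set()

    def test_solvent_and_hydrogens_ignored(self):
        h_atom = ("LEU", 40, "HA", False, "receptor", [0.0, 0.0, 1.0])
        traj = toy_trajectory([[0.0, 0.0, 3.0]], [WATER, h_atom])
        assert contacts_in_frame(traj, 0) == set()

    def test_matches_brute_force_all_pairs_scan(self, rng):
        """On a random 50-atom, 20-frame toy the contact sets equal an
        independent double-loop distance scan, frame by frame."""
        atoms = []
        cats = ["receptor", "ligand", "lipid", "solvent"]
        resnames = {"receptor": "ALA", "ligand": "GLY", "lipid": "DMPC", "solvent": "HOH"}
        for i in range(50):
            cat = cats[i % 4]
            atoms.append((resnames[cat], i + 1, "C1", bool(i % 3), cat,
                          rng.uniform(-12, 12, 3).tolist()))
        xe = rng.uniform(-12, 12, (20, 3))
        traj = toy_trajectory(xe.tolist(), atoms)
        for f in range(20):
            expected = set()
            for a in atoms:
                if a[4] in ("receptor", "ligand", "lipid") and a[3]:
                    d = np.sqrt(sum((xe[f][k] - a[5][k]) ** 2 for k in range(3)))
                    if d < 8.5:
                        expected.add((a[4], residue_label(a[0], a[1])))
            assert contacts_in_frame(traj, f, 8.5) == expected

    def test_missing_xenon_rejected(self):
        with pytest.raises(ValueError, match="xenon"):
            Trajectory(
                coords=np.zeros((1, 1, 3)),
                times_ns=np.array([1.0]),
                resids=np.array([1]),
                resnames=np.array(["ALA"]),
                names=np.array(["CA"]),
                heavy=np.array([True]),
                category=np.array(["receptor"]),
            )


class TestBuildContactTable:
    def test_never_in_contact_is_all_no_contacts(self):
        traj = toy_trajectory([[100.0] * 3] * 5, [LEU, DMPC])
        table = build_contact_table(traj, discard_ns=0.0)
        assert table.category_probabilities()["no contacts"] == 1.0

    def test_simultaneous_lipid_and_protein_single_category(self):
        # xenon 5 A from the receptor atom and ~6.4 A from a nearby lipid
        lipid_close = ("DMPC", 2, "C2", True, "lipid", [0.0, 8.0, 0.0])
        traj = toy_trajectory([[0.0, 4.0, 3.0]], [LEU, lipid_close])
        table = build_contact_table(traj, discard_ns=0.0)
        assert table.frame_categories == ("lipid and protein",)
        probs = table.category_probabilities()
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_counts_monotone_in_cutoff(self, rng):
        atoms = [("ALA", i + 1, "CB", True, "receptor", rng.uniform(-15, 15, 3).tolist())
                 for i in range(10)]
        traj = toy_trajectory(rng.uniform(-15, 15, (30, 3)).tolist(), atoms)
        small = build_contact_table(traj, cutoff=6.0, discard_ns=0.0)
        large = build_contact_table(traj, cutoff=10.0, discard_ns=0.0)
        for key, cnt in small.counts.items():
            assert large.counts.get(key, 0) >= cnt

    def test_equilibration_discard(self):
        traj = toy_trajectory([[0.0, 0.0, 3.0]] * 10, [LEU])
        table = build_contact_table(traj, discard_ns=5.0)
        assert table.n_frames == 6  # times 1..10 ns, keep >= 5 ns
        with pytest.raises(ValueError, match="equilibration"):
            build_contact_table(traj, discard_ns=100.0)

    def test_markov_categories_match_stationary_distribution(self):
        """Category frequencies of the 3-site hopping chain match the
        analytic stationary vector within 3 chain-aware standard errors
        at 1e4 frames."""
        model = default_hop_model()
        n = 10_000
        traj, truth = gen_hop_trajectory(model, n_frames=n, seed=42)
        table = build_contact_table(traj, discard_ns=0.0)
        probs = table.category_probabilities()
        P, pi = model.transition, stationary_distribution(model.transition)
        for s, p_true in zip(model.states, pi):
            # asymptotic variance of the occupation frequency of one
            # state of a Markov chain: pi(1-pi) + 2*sum_t (pi P^t - pi^2)
            idx = model.states.index(s)
            gamma = pi[idx] * (1 - pi[idx])
            Pt = np.eye(len(pi))
            acc = gamma
            for _ in range(200):
                Pt = Pt @ P
                acc += 2 * (pi[idx] * Pt[idx, idx] - pi[idx] ** 2)
            se = np.sqrt(acc / n)
            assert abs(probs[s.category] - p_true) < 3 * se

    def test_interface_model_populates_all_categories(self):
        traj, truth = gen_hop_trajectory(interface_hop_model(), n_frames=3000, seed=3)
        probs = build_contact_table(traj, discard_ns=0.0).category_probabilities()
        for cat, p_true in truth["category_probs"].items():
            assert probs[cat] == pytest.approx(p_true, abs=0.05)


def table_from_probs(probs, n_frames=1000):
    counts = {("receptor", f"A{i + 1}"): int(round(p * n_frames))
              for i, p in enumerate(probs)}
    return ContactTable(
        counts=counts,
        frame_categories=("just protein",) * n_frames,
        n_frames=n_frames,
        cutoff=8.5,
        equilibration_discard_ns=0.0,
    )


class TestSiteProbability:
    def test_uncontacted_cluster_is_zero(self):
        table = table_from_probs([0.5])
        cluster = SiteCluster("ECL1", ("L112", "M113", "G114"))
        assert site_contact_probability(table, cluster) == 0.0

    def test_fully_contacted_cluster_is_one(self):
        table = table_from_probs([1.0, 1.0, 1.0])
        cluster = SiteCluster("NTER", ("A1", "A2", "A3"))
        assert site_contact_probability(table, cluster) == 1.0

    def test_top3_mean_of_four_residues(self):
        """Per-residue probabilities (0.6, 0.4, 0.2, 0.1) -> mean of the
        top three = 0.4."""
        table = table_from_probs([0.6, 0.4, 0.2, 0.1])
        cluster = SiteCluster("S", ("A1", "A2", "A3", "A4"))
        assert site_contact_probability(table, cluster) == pytest.approx(0.4)

    def test_small_cluster_warns(self):
        table = table_from_probs([0.6, 0.4])
        with pytest.warns(UserWarning, match="averaging"):
            p = site_contact_probability(table, SiteCluster("S", ("A1", "A2")))
        assert p == pytest.approx(0.5)


class TestProjectionNormalization:
    def test_counts_scaled_by_maximum(self):
        table = table_from_probs([0.002, 0.004, 0.008])
        out = normalize_counts_for_projection(table)
        assert sorted(out.values()) == [0.25, 0.5, 1.0]

    def test_scale_invariance(self):
        t1 = table_from_probs([0.002, 0.004, 0.008], n_frames=1000)
        t2 = table_from_probs([0.002, 0.004, 0.008], n_frames=2000)
        assert normalize_counts_for_projection(t1) == normalize_counts_for_projection(t2)

    def test_all_zero_rejected(self):
        table = table_from_probs([0.0])
        with pytest.raises(ValueError):
            normalize_counts_for_projection(table)
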