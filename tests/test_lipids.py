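"""Centering/dewrapping, density maps, radial stoichiometry and diffusion."""
import numpy as np
import pandas as pd
import pytest

from helixpack import lipids, synthetic
from helixpack.core import ContractError, Structure, Trajectory


def _bead_system(positions, types=None, box=(200.0, 200.0, 80.0),
                 leaflet="upper", protein_at=(0.0, 0.0, 0.0)):
    """One protein bead + lipid beads at given positions (single frame)."""
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    types = types or ["PC"] * n
    lips = Structure(
        atom_name=np.array(["P"] * n, dtype=object),
        element=np.array(["P"] * n, dtype=object),
        res_name=np.array(types, dtype=object),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(["U" if leaflet == "upper" else "L"] * n,
                          dtype=object),
        coords=positions,
    )
    prot = Structure(
        atom_name=np.array(["CA"], dtype=object),
        element=np.array(["C"], dtype=object),
        res_name=np.array(["ALA"], dtype=object),
        res_id=np.array([1]),
        chain_id=np.array(["A"], dtype=object),
        coords=np.array([protein_at], float),
    )
    topo = Structure.concat([lips, prot])
    table = pd.DataFrame({
        "lipid_id": np.arange(1, n + 1),
        "type": types,
        "leaflet": [leaflet] * n,
        "anionic": [t in synthetic.ANIONIC_TYPES for t in types],
        "area_weight": [2 if t == "CL" else 1 for t in types],
        "atom_index": np.arange(n),
    })
    return topo, table


def _traj(topo, frames, box=(200.0, 200.0, 80.0), dt=100.0):
    coords = np.asarray(frames, float)
    return Trajectory(topology=topo, coords=coords,
                      times=dt * np.arange(coords.shape[0]),
                      box=np.tile(box, (coords.shape[0], 1)))


class TestCenterAndDewrap:
    def test_centered_driftless_input_unchanged(self):
        topo, _ = _bead_system([[90.0, 100.0, 59.0], [110.0, 100.0, 59.0]],
                               protein_at=(100.0, 100.0, 40.0))
        traj = _traj(topo, [topo.coords] * 3)
        out = lipids.center_and_dewrap(traj, {"chain": "A"})
        np.testing.assert_allclose(out.coords, traj.coords, atol=1e-12)
        np.testing.assert_allclose(out.unwrapped, traj.coords, atol=1e-12)

    def test_uniform_drift_removed_relative_positions_kept(self):
        topo, _ = _bead_system([[90.0, 100.0, 59.0], [120.0, 90.0, 59.0]],
                               protein_at=(100.0, 100.0, 40.0))
        frames = [topo.coords + np.array([k * 1.0, 0.0, 0.0])
                  for k in range(5)]
        out = lipids.center_and_dewrap(_traj(topo, frames), {"chain": "A"})
        prot = out.topology.mask(chain="A")
        centroids = out.coords[:, prot, :].mean(axis=1)
        assert np.ptp(centroids, axis=0).max() < 1e-9
        rel = out.coords[:, 0, :] - out.coords[:, 1, :]
        assert np.ptp(rel, axis=0).max() < 1e-9

    def test_boundary_crossing_unwraps_continuously(self):
        # lipid marches +2 Å/frame in x across the +x boundary
        topo, _ = _bead_system([[195.0, 100.0, 59.0]],
                               protein_at=(100.0, 100.0, 40.0))
        frames = []
        for k in range(6):
            f = topo.coords.copy()
            f[0, 0] = (195.0 + 2.0 * k) % 200.0
            frames.append(f)
        out = lipids.center_and_dewrap(_traj(topo, frames), {"chain": "A"})
        x = out.unwrapped[:, 0, 0]
        np.testing.assert_allclose(np.diff(x), 2.0, atol=1e-9)

    def test_empty_protein_selection_rejected(self):
        topo, _ = _bead_system([[90.0, 100.0, 59.0]])
        traj = _traj(topo, [topo.coords])
        with pytest.raises(ContractError):
            lipids.center_and_dewrap(traj, {"chain": "Z"})


class TestDensityMap:
    def test_uniform_lipids_give_flat_map(self):
        rng = np.random.default_rng(8)
        n = 400
        pos = np.column_stack([rng.uniform(0, 200, n), rng.uniform(0, 200, n),
                               np.full(n, 59.0)])
        topo, table = _bead_system(pos, protein_at=(100.0, 100.0, 40.0))
        traj = lipids.center_and_dewrap(_traj(topo, [topo.coords]),
                                        {"chain": "A"})
        dm = lipids.density_map(traj, table, "PC", spacing=25.0)
        lam = dm.values.mean()
        # Poisson: a flat field's max deviation stays within 5 sqrt(lambda)
        assert np.abs(dm.values - lam).max() < 5.0 * np.sqrt(lam)

    def test_point_mass_occupies_single_cell(self):
        pos = np.tile([123.0, 77.0, 59.0], (6, 1))
        topo, table = _bead_system(pos, protein_at=(100.0, 100.0, 40.0))
        traj = lipids.center_and_dewrap(_traj(topo, [topo.coords]),
                                        {"chain": "A"})
        dm = lipids.density_map(traj, table, "PC", spacing=2.0)
        assert (dm.values > 0).sum() == 1
        assert dm.total_mass == pytest.approx(6.0)

    def test_total_mass_equals_mean_lipid_count(self, brownian_run):
        traj, table, _ = brownian_run
        for lt in ("PC", "CL"):
            dm = lipids.density_map(traj, table, lt, window_ns=(0, 10),
                                    spacing=5.0)
            expected = (table["type"] == lt).sum()
            assert dm.total_mass == pytest.approx(expected, rel=1e-6)

    def test_enriched_run_concentrates_cl_near_protein(self, enrichment_runs):
        runs, table = enrichment_runs
        half_ns = runs["biased"].times[-1] / 2000.0
        masses = {}
        for label, traj in runs.items():
            dm = lipids.density_map(traj, table, "CL",
                                    window_ns=(half_ns, 2 * half_ns),
                                    spacing=5.0)
            masses[label] = dm.mass_within(20.0)
        assert masses["biased"] > masses["unbiased"]


class TestRadialStoichiometry:
    def test_empty_disc_counts_zero(self):
        topo, table = _bead_system([[10.0, 10.0, 59.0]],
                                   protein_at=(100.0, 100.0, 40.0))
        traj = lipids.center_and_dewrap(_traj(topo, [topo.coords]),
                                        {"chain": "A"})
        rep = lipids.radial_stoichiometry(traj, table, {"chain": "A"})
        assert (rep.per_type["mean"] == 0).all()

    def test_hand_checked_area_weighted_percentage(self):
        types = ["CL", "CL", "PS", "PS", "PS", "PC"]
        pos = np.array([[105, 100, 59], [100, 105, 59], [103, 103, 59],
                        [96, 100, 59], [100, 96, 59], [106, 106, 59]], float)
        topo, table = _bead_system(pos, types=types,
                                   protein_at=(100.0, 100.0, 40.0))
        traj = lipids.center_and_dewrap(_traj(topo, [topo.coords]),
                                        {"chain": "A"})
        rep = lipids.radial_stoichiometry(traj, table, {"chain": "A"},
                                          cutoff=20.0)
        counts = dict(zip(rep.per_type["type"], rep.per_type["mean"]))
        assert counts == {"CL": 2.0, "PC": 1.0, "PS": 3.0}
        # (2·2 + 3·1) / (2·2 + 3·1 + 1·1) = 87.5 %
        assert rep.anionic_percent_mean == pytest.approx(87.5)
        assert rep.neutral_percent_mean == pytest.approx(12.5)

    def test_stationary_windows_have_zero_sd(self):
        topo, table = _bead_system([[105.0, 100.0, 59.0], [90.0, 95.0, 59.0]],
                                   protein_at=(100.0, 100.0, 40.0))
        traj = lipids.center_and_dewrap(
            _traj(topo, [topo.coords] * 30, dt=1000.0), {"chain": "A"})
        rep = lipids.radial_stoichiometry(
            traj, table, {"chain": "A"},
            windows_ns=[(0, 9), (10, 19), (20, 29)])
        assert (rep.per_type["sd"] == 0).all()

    def test_invariant_under_global_lateral_translation(self):
        types = ["CL", "PS", "PC", "PE"]
        pos = np.array([[105, 100, 59], [100, 105, 59], [92, 100, 59],
                        [150, 30, 59]], float)
        topo, table = _bead_system(pos, types=types,
                                   protein_at=(100.0, 100.0, 40.0))
        base = lipids.radial_stoichiometry(
            lipids.center_and_dewrap(_traj(topo, [topo.coords]),
                                     {"chain": "A"}),
            table, {"chain": "A"})
        shifted = topo.copy()
        shifted.coords = (shifted.coords + [37.0, -12.0, 0.0])
        shifted.coords[:, 0] %= 200.0
        shifted.coords[:, 1] %= 200.0
        moved = lipids.radial_stoichiometry(
            lipids.center_and_dewrap(_traj(shifted, [shifted.coords]),
                                     {"chain": "A"}),
            table, {"chain": "A"})
        pd.testing.assert_frame_equal(base.per_type, moved.per_type)

    def test_area_weight_changes_percentages_not_counts(self):
        types = ["CL", "PS", "PC"]
        pos = np.array([[105, 100, 59], [100, 105, 59], [96, 100, 59]], float)
        topo, table = _bead_system(pos, types=types,
                                   protein_at=(100.0, 100.0, 40.0))
        traj = lipids.center_and_dewrap(_traj(topo, [topo.coords]),
                                        {"chain": "A"})
        with_weight = lipids.radial_stoichiometry(traj, table, {"chain": "A"})
        flat = table.copy()
        flat["area_weight"] = 1
        without = lipids.radial_stoichiometry(traj, flat, {"chain": "A"})
        pd.testing.assert_frame_equal(with_weight.per_type, without.per_type)
        assert with_weight.anionic_percent_mean != without.anionic_percent_mean


class TestLateralDiffusion:
    def test_immobile_lipids_have_zero_d(self):
        topo, table = _bead_system([[90.0, 100.0, 59.0], [60.0, 80.0, 59.0]],
                                   protein_at=(100.0, 100.0, 40.0))
        traj = lipids.center_and_dewrap(
            _traj(topo, [topo.coords] * 100, dt=10.0), {"chain": "A"})
        for est in lipids.lateral_diffusion(traj, table):
            assert est.d_mean_A2_ps == pytest.approx(0.0, abs=1e-12)

    def test_known_d_recovered_within_ten_percent(self, brownian_run):
        traj, table, params = brownian_run
        for est in lipids.lateral_diffusion(traj, table, windows_ns=[(0, 50)]):
            truth = params.diffusion[est.lipid_type]
            assert abs(est.d_mean_A2_ps - truth) / truth < 0.10
            assert not est.poor_fit

    def test_consecutive_windows_agree_within_two_sd(self, brownian_run):
        traj, table, _ = brownian_run
        est = lipids.lateral_diffusion(
            traj, table, windows_ns=[(20, 30), (30, 40), (40, 50)])
        for lt in ("PC", "CL"):
            vals = [(e.d_mean_A2_ps, e.d_sd_A2_ps / np.sqrt(e.n_molecules))
                    for e in est if e.lipid_type == lt]
            for (m1, s1) in vals:
                for (m2, s2) in vals:
                    assert abs(m1 - m2) <= 2.0 * np.sqrt(s1 ** 2 + s2 ** 2) + 1e-12

    def test_ballistic_drift_flagged_as_poor_fit(self):
        topo, table = _bead_system([[10.0, 100.0, 59.0]],
                                   protein_at=(100.0, 100.0, 40.0))
        frames = []
        for k in range(200):
            f = topo.coords.copy()
            f[0, 0] += 0.5 * k          # constant velocity => MSD ∝ τ²
            frames.append(f)
        traj = _traj(topo, frames, box=(1000.0, 1000.0, 80.0), dt=10.0)
        traj = Trajectory(topology=topo, coords=traj.coords, times=traj.times,
                          box=traj.box, unwrapped=traj.coords.copy())
        est = lipids.lateral_diffusion(traj, table)
        assert est[0].poor_fit

    def test_too_few_lag_points_rejected(self):
        topo, table = _bead_system([[90.0, 100.0, 59.0]])
        traj = lipids.center_and_dewrap(
            _traj(topo, [topo.coords] * 6, dt=10.0), {"chain": "U"})
        with pytest.raises(ContractError):
            lipids.lateral_diffusion(traj, table, windows_ns=[(0, 0.05)])

    def test_unwrapped_coordinates_required(self):
        topo, table = _bead_system([[90.0, 100.0, 59.0]])
        traj = _traj(topo, [topo.coords] * 100, dt=10.0)
        with pytest.raises(ContractError):
            lipids.lateral_diffusion(traj, table)
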