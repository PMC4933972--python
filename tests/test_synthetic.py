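"""Generators: ideal helices, docked dimers, membranes, Brownian walks,
rotation schedules and analytic surfaces, against their declared ground truth."""
import numpy as np
import pytest
from scipy.spatial.distance import cdist

from helixpack import fes, geometry, synthetic
from helixpack.core import ContractError


class TestIdealHelix:
    def test_ca_span_forced_by_rise(self, ideal_helix):
        ca = ideal_helix.coords[ideal_helix.mask(atom_name="CA")]
        span = ca[:, 2].max() - ca[:, 2].min()
        assert span == pytest.approx(20 * 1.5, abs=1e-3)

    def test_glycine_179_has_no_cb(self, ideal_helix):
        assert not ideal_helix.mask(res_id=179, atom_name="CB").any()
        assert ideal_helix.mask(res_id=179, atom_name="CA").any()

    def test_canonical_dihedrals_give_full_helicity(self, ideal_helix):
        assert geometry.helicity(ideal_helix, "A") == 100.0

    def test_custom_rise_and_twist_are_honored(self):
        spec = synthetic.HelixSpec(rise_per_residue=1.45,
                                   twist_per_residue=98.0)
        st = synthetic.build_ideal_helix(spec)
        ca = st.coords[st.mask(atom_name="CA")]
        np.testing.assert_allclose(np.diff(ca[:, 2]), 1.45, atol=1e-4)

    def test_unknown_amino_acid_rejected(self):
        with pytest.raises(ContractError):
            synthetic.HelixSpec(sequence="AXW")


class TestDimerFixtures:
    def test_declared_pairs_crosslinkable(self, dimer_fixtures):
        for name, st in dimer_fixtures.items():
            pairs = synthetic.DIMER_STATES[name].crosslink_pairs
            for rep in geometry.cb_distance_series(st, pairs):
                assert rep.distance_series[0] <= synthetic.CROSSLINK_MAX

    def test_no_intermonomer_clash(self, dimer_fixtures):
        for st in dimer_fixtures.values():
            a = st.mask(chain="A")
            assert cdist(st.coords[a], st.coords[~a]).min() >= \
                synthetic.CLASH_CUTOFF - 1e-9

    def test_states_not_superimposable(self, dimer_fixtures):
        names = list(dimer_fixtures)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                rmsd = geometry.backbone_rmsd(dimer_fixtures[a],
                                              dimer_fixtures[b])
                assert rmsd > 2.0

    def test_same_seed_reproducible(self, dimer_fixtures):
        again = synthetic.build_dimer_fixture("parallel", seed=0)
        np.testing.assert_array_equal(again.coords,
                                      dimer_fixtures["parallel"].coords)

    def test_membrane_normal_along_z(self, dimer_fixtures):
        for st in dimer_fixtures.values():
            mean_dir = sum(geometry.fit_helix_axis(st, c).direction
                           for c in "AB")
            mean_dir /= np.linalg.norm(mean_dir)
            assert mean_dir @ [0, 0, 1] > 0.999


class TestA183I:
    def test_pseudo_atom_on_both_chains(self, dimer_fixtures):
        mut = synthetic.apply_mutation_A183I(dimer_fixtures["intersected"])
        cg = mut.mask(atom_name="CG1")
        assert sorted(mut.chain_id[cg]) == ["A", "B"]
        assert set(mut.res_name[mut.mask(res_id=183)]) == {"ILE"}

    def test_iso_parallel_t186_distance_increases(self, dimer_fixtures,
                                                  iso_mutant):
        before = geometry.cb_distance_series(
            dimer_fixtures["iso_parallel"], [186])[0].distance_series[0]
        after = geometry.cb_distance_series(
            iso_mutant, [186])[0].distance_series[0]
        assert after > before

    def test_mutant_remains_clash_free(self, iso_mutant):
        a = iso_mutant.mask(chain="A")
        ra = np.where(iso_mutant.atom_name[a] == "CG1",
                      synthetic.PSEUDO_VDW_RADIUS, synthetic.ATOM_CLASH_RADIUS)
        rb = np.where(iso_mutant.atom_name[~a] == "CG1",
                      synthetic.PSEUDO_VDW_RADIUS, synthetic.ATOM_CLASH_RADIUS)
        gap = cdist(iso_mutant.coords[a], iso_mutant.coords[~a]) \
            - (ra[:, None] + rb[None, :])
        assert gap.min() >= -1e-6

    def test_requires_alanine_183(self, iso_mutant):
        with pytest.raises(ContractError):
            synthetic.apply_mutation_A183I(iso_mutant)  # already ILE


class TestMembrane:
    def test_default_composition_1000_lipids_exact(self):
        _, table = synthetic.build_membrane(n_lipids=1000, box_xy=320.0,
                                            seed=0)
        counts = table.groupby("type").size().to_dict()
        assert counts == {"PC": 465, "PE": 284, "PI": 89, "PS": 89, "CL": 73}

    def test_single_type_composition(self):
        comp = synthetic.MembraneComposition({"PC": 1.0})
        _, table = synthetic.build_membrane(comp, n_lipids=10, box_xy=60.0,
                                            seed=0)
        assert (table["type"] == "PC").all() and len(table) == 10

    def test_largest_remainder_at_200(self):
        _, table = synthetic.build_membrane(n_lipids=200, box_xy=150.0, seed=0)
        counts = table.groupby("type").size()
        assert counts.sum() == 200
        fractions = synthetic.MembraneComposition().fractions
        for t, c in counts.items():
            assert abs(c / 200 - fractions[t]) <= 0.005

    def test_odd_lipid_count_rejected(self):
        with pytest.raises(synthetic.PackingError):
            synthetic.build_membrane(n_lipids=201, box_xy=200.0, seed=0)

    def test_box_too_small_rejected(self):
        with pytest.raises(synthetic.PackingError):
            synthetic.build_membrane(n_lipids=100, box_xy=20.0, seed=0)

    def test_same_seed_identical_and_no_overlap(self):
        m1, t1 = synthetic.build_membrane(n_lipids=60, box_xy=100.0, seed=4)
        m2, _ = synthetic.build_membrane(n_lipids=60, box_xy=100.0, seed=4)
        np.testing.assert_array_equal(m1.coords, m2.coords)
        for leaf in ("U", "L"):
            xy = m1.coords[m1.mask(chain=leaf)][:, :2]
            delta = xy[:, None, :] - xy[None, :, :]
            delta -= 100.0 * np.round(delta / 100.0)
            dp = np.linalg.norm(delta, axis=-1)
            np.fill_diagonal(dp, np.inf)
            assert dp.min() >= 6.0

    def test_area_weight_marks_cardiolipin_only(self):
        _, table = synthetic.build_membrane(n_lipids=200, box_xy=150.0, seed=0)
        assert ((table["area_weight"] == 2) == (table["type"] == "CL")).all()


class TestBrownianWalk:
    def test_zero_diffusion_freezes_all_frames(self):
        membrane, table = synthetic.build_membrane(n_lipids=20, box_xy=80.0,
                                                   seed=0)
        params = synthetic.BrownianParams(
            diffusion={t: 0.0 for t in synthetic.LIPID_TYPES}, n_steps=5,
            seed=0)
        traj = synthetic.simulate_lipid_trajectory(membrane, table, params)
        for k in range(1, traj.n_frames):
            np.testing.assert_array_equal(traj.coords[k], traj.coords[0])

    def test_bitwise_reproducible(self):
        membrane, table = synthetic.build_membrane(n_lipids=20, box_xy=80.0,
                                                   seed=0)
        params = synthetic.BrownianParams(n_steps=50, seed=5)
        t1 = synthetic.simulate_lipid_trajectory(membrane, table, params)
        t2 = synthetic.simulate_lipid_trajectory(membrane, table, params)
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_enrichment_accumulates_cl_near_protein(self, enrichment_runs):
        runs, table = enrichment_runs
        cl = table[table["type"] == "CL"]["atom_index"].to_numpy()
        counts = {}
        for label, traj in runs.items():
            late = traj.times >= traj.times[-1] / 2
            center = traj.box[0, :2] / 2
            inside = 0.0
            for k in np.flatnonzero(late):
                d = np.linalg.norm(traj.coords[k][cl, :2] - center, axis=1)
                inside += (d <= 20.0).sum()
            counts[label] = inside / late.sum()
        assert counts["biased"] > counts["unbiased"]


class TestCVRotation:
    def test_zero_schedule_is_identity(self, dimer_fixtures):
        d = dimer_fixtures["intersected"]
        traj = synthetic.simulate_cv_rotation(d, [0.0, 0.0], [0.0, 0.0])
        for k in range(traj.n_frames):
            np.testing.assert_allclose(traj.coords[k], d.coords, atol=1e-12)

    def test_single_rotation_recovered(self, dimer_fixtures):
        d = dimer_fixtures["intersected"]
        traj = synthetic.simulate_cv_rotation(d, [30.0], [0.0])
        cv = geometry.rotation_cv(traj.frame(0), d)
        assert cv.alpha == pytest.approx(30.0, abs=2.0)
        assert cv.beta == pytest.approx(0.0, abs=2.0)

    def test_final_frame_of_ramp_reads_end_angles(self, dimer_fixtures):
        d = dimer_fixtures["intersected"]
        traj = synthetic.simulate_cv_rotation(
            d, np.linspace(0, 70, 5), np.linspace(0, 90, 5))
        cv = geometry.rotation_cv(traj.frame(4), d)
        assert cv.alpha == pytest.approx(70.0, abs=2.0)
        assert cv.beta == pytest.approx(90.0, abs=2.0)

    def test_unequal_schedules_rejected(self, dimer_fixtures):
        with pytest.raises(ContractError):
            synthetic.simulate_cv_rotation(dimer_fixtures["intersected"],
                                           [0.0, 1.0], [0.0])


class TestAnalyticFES:
    def test_single_basin_minimum_at_center(self):
        grid = synthetic.make_analytic_fes(
            [{"center": (10.0, -5.0), "depth": 4.0, "width": 8.0}],
            alpha_range=(-30, 50), beta_range=(-45, 35), spacing=1.0)
        i, j = np.unravel_index(np.argmin(grid.energy), grid.shape)
        assert grid.cell_center((i, j)) == pytest.approx((10.0, -5.0), abs=1.0)
        assert grid.minimum_shifted and grid.energy.min() == 0.0

    def test_empty_basin_list_rejected(self):
        with pytest.raises(ContractError):
            synthetic.make_analytic_fes([])

    def test_two_equal_basins_saddle_at_midpoint(self):
        grid = synthetic.make_analytic_fes(
            [{"center": (0.0, 0.0), "depth": 5.0, "width": 10.0},
             {"center": (50.0, 0.0), "depth": 5.0, "width": 10.0}],
            alpha_range=(-30, 80), beta_range=(-30, 30), spacing=1.0)
        saddle = grid.metadata["line_saddles"][0]
        assert saddle["alpha"] == pytest.approx(25.0, abs=0.1)
        # closed form: both wells contribute equally at the midpoint
        expected = -2 * 5.0 * np.exp(-(25.0 ** 2) / (2 * 10.0 ** 2))
        assert saddle["energy_unshifted"] == pytest.approx(expected, rel=1e-3)

    def test_six_state_path_visits_major_states_in_order(self):
        grid = synthetic.six_state_fes()
        states = fes.detect_states(grid, min_depth=0.5)
        assert len(states) == 6
        oracle = fes.dijkstra_path_oracle(grid, (0, 0), (70, 90))
        by_cell = {}
        for s in states:
            for c in s.basin_cells:
                by_cell[c] = s.label
        visited = []
        for c in oracle.cells:
            lab = by_cell.get(c)
            if lab and (not visited or visited[-1] != lab):
                visited.append(lab)
        majors = [v for v in visited if v in ("I", "II", "IV", "VI")]
        assert majors == ["I", "II", "IV", "VI"]
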