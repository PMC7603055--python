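import numpy as np
import pytest

from somscape import (
    ExpressionMatrix,
    Portrait,
    SOMGrid,
    detect_attractors,
    fit_gamma,
    grid_vector_field,
    metagene_velocity,
    velocity_trajectories,
)
from somscape.simulate import generate_differentiation, true_velocity
from somscape.som import SOMModel
from somscape.velocity import VelocityField, _bilinear_arrow


def _layers(s_vals, u_vals):
    s_vals = np.atleast_2d(np.asarray(s_vals, dtype=float))
    u_vals = np.atleast_2d(np.asarray(u_vals, dtype=float))
    genes = [f"g{i}" for i in range(s_vals.shape[0])]
    cells = [f"c{j}" for j in range(s_vals.shape[1])]
    return (
        ExpressionMatrix(s_vals, genes, cells, "spliced"),
        ExpressionMatrix(u_vals, genes, cells, "unspliced"),
    )


class TestFitGamma:
    def test_exact_steady_state_gives_gamma_and_zero_velocity(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(1, 10, size=(5, 40))
        u = 2.0 * s
        sm, um = _layers(s, u)
        kin = fit_gamma(sm, um)
        np.testing.assert_allclose(kin.gamma, 2.0)
        np.testing.assert_allclose(kin.velocity, 0.0, atol=1e-10)

    def test_velocity_arithmetic_with_known_gamma(self):
        # u = 3, s = 1, gamma fitted through origin on a single cell = 3;
        # with a second steady-state cell pinning gamma = 2, v = 3 - 2*1 = 1
        sm, um = _layers([[1.0, 10.0]], [[3.0, 20.0]])
        kin = fit_gamma(sm, um, quantile=0.5)
        # slope through origin over both cells: (3+200)/(1+100)
        assert kin.gamma[0] == pytest.approx(203.0 / 101.0)
        assert kin.velocity[0, 0] == pytest.approx(3.0 - kin.gamma[0] * 1.0)

    def test_all_zero_spliced_gene_flagged_unfittable(self):
        sm, um = _layers([[0.0, 0.0], [1.0, 2.0]], [[1.0, 1.0], [1.0, 2.0]])
        kin = fit_gamma(sm, um, quantile=0.5)
        assert not kin.fitted[0] and kin.fitted[1]
        assert np.all(np.isnan(kin.velocity[0]))

    def test_steady_state_generator_recovers_gamma_within_1pct(self):
        data = generate_differentiation(
            n_cells=300, n_genes=300, n_lineages=2, seed=3, steady_state=True
        )
        kin = fit_gamma(data.spliced, data.unspliced, quantile=0.05)
        expected = (
            data.truth.kinetics["gamma_true"] / data.truth.kinetics["beta"]
        ).to_numpy()
        rel = np.abs(kin.gamma - expected) / expected
        assert np.nanmax(rel) < 0.01
        assert np.nanmax(np.abs(kin.velocity)) < 1e-8

    def test_induced_genes_have_positive_velocity_mid_trajectory(self):
        data = generate_differentiation(n_cells=500, n_genes=600, n_lineages=2, seed=4)
        kin = fit_gamma(data.spliced, data.unspliced, quantile=0.05)
        vt = true_velocity(data)
        t = data.truth.latent_time.to_numpy()
        mods = data.truth.gene_module.to_numpy()
        lin = data.truth.lineage.to_numpy()
        mid = (t > 0.2) & (t < 0.8)
        agree = []
        for li in (1, 2):
            rows = mods == f"tissue_{li}"
            cols = mid & (lin == f"tissue_{li}")
            est = kin.velocity[np.ix_(rows, cols)]
            ref = vt[np.ix_(rows, cols)]
            assert np.all(ref > 0)  # induction: truth is strictly rising
            agree.append((np.sign(est) == 1).mean())
        assert min(agree) >= 0.95

    def test_mismatched_layers_rejected(self):
        sm, um = _layers([[1.0, 2.0]], [[1.0, 2.0]])
        with pytest.raises(ValueError, match="spliced"):
            fit_gamma(um, sm)


class TestMetageneVelocity:
    def _model_with_bmu(self, bmu, n_cells=4):
        grid = SOMGrid(2, 2)
        return SOMModel(
            grid=grid,
            prototypes=np.zeros((4, n_cells)),
            bmu=np.asarray(bmu),
            gene_ids=[f"g{i}" for i in range(len(bmu))],
            cell_ids=[f"c{j}" for j in range(n_cells)],
        )

    def _kin(self, velocity, gamma=None):
        velocity = np.asarray(velocity, dtype=float)
        from somscape.velocity import GeneKinetics

        g = np.ones(velocity.shape[0]) if gamma is None else np.asarray(gamma)
        return GeneKinetics(
            gene_ids=[f"g{i}" for i in range(velocity.shape[0])],
            cell_ids=[f"c{j}" for j in range(velocity.shape[1])],
            gamma=g,
            velocity=velocity,
            fit_quantile=0.05,
        )

    def test_single_member_node_carries_gene_row(self):
        model = self._model_with_bmu([2])
        kin = self._kin([[1.0, -1.0, 2.0, 0.0]])
        nv, has = metagene_velocity(model, kin)
        np.testing.assert_array_equal(nv[2], [1.0, -1.0, 2.0, 0.0])
        assert has[2] and not has[0]
        np.testing.assert_array_equal(nv[0], 0.0)

    def test_opposite_members_cancel(self):
        model = self._model_with_bmu([1, 1])
        v = np.array([[1.0, 2.0, -1.0, 0.5], [-1.0, -2.0, 1.0, -0.5]])
        nv, _ = metagene_velocity(model, self._kin(v))
        np.testing.assert_allclose(nv[1], 0.0)

    def test_matches_recomputed_group_means(self, small_sim, small_model):
        kin = fit_gamma(small_sim.spliced, small_sim.unspliced)
        nv, has = metagene_velocity(small_model, kin)
        node = int(small_model.bmu[np.flatnonzero(kin.fitted)[0]])
        members = [
            i
            for i, g in enumerate(small_model.gene_ids)
            if small_model.bmu[i] == node and kin.fitted[i]
        ]
        np.testing.assert_allclose(nv[node], kin.velocity[members].mean(axis=0))
        assert has[node]

    def test_unfittable_genes_excluded(self):
        model = self._model_with_bmu([0, 0])
        v = np.array([[1.0, 1.0, 1.0, 1.0], [np.nan] * 4])
        kin = self._kin(v, gamma=[1.0, np.nan])
        nv, has = metagene_velocity(model, kin)
        np.testing.assert_array_equal(nv[0], [1.0, 1.0, 1.0, 1.0])


class TestGridVectorField:
    def test_velocity_aligned_with_one_neighbor_points_there(self):
        rng = np.random.default_rng(0)
        grid = SOMGrid(3, 3)
        protos = rng.normal(size=(9, 30))
        model = SOMModel(
            grid=grid,
            prototypes=protos,
            bmu=np.zeros(0, dtype=int),
            gene_ids=[],
            cell_ids=[f"c{j}" for j in range(30)],
        )
        center = grid.node_index(1, 1)
        target = grid.node_index(1, 2)
        # velocity = target delta orthogonalized against every other
        # neighbor delta (centered), so only the target correlates
        deltas = {
            n: (protos[n] - protos[center]) - (protos[n] - protos[center]).mean()
            for n in grid.neighbors8(center)
        }
        others = np.array([d for n, d in deltas.items() if n != target])
        q, _ = np.linalg.qr(others.T)
        v = deltas[target] - q @ (q.T @ deltas[target])
        nv = np.zeros((9, 30))
        nv[center] = v
        field = grid_vector_field(model, nv)
        arrow = field.arrows[center]
        direction = arrow / np.linalg.norm(arrow)
        np.testing.assert_allclose(direction, [0.0, 1.0], atol=1e-6)

    def test_zero_velocity_gives_zero_arrow(self, small_model):
        nv = np.zeros((small_model.grid.n_nodes, small_model.n_cells))
        field = grid_vector_field(small_model, nv)
        np.testing.assert_array_equal(field.arrows, 0.0)

    def test_arrow_length_bounded_by_one(self, small_sim, small_model):
        kin = fit_gamma(small_sim.spliced, small_sim.unspliced)
        nv, has = metagene_velocity(small_model, kin)
        field = grid_vector_field(small_model, nv, has)
        assert np.linalg.norm(field.arrows, axis=1).max() <= 1.0 + 1e-12

    def test_scaling_velocities_preserves_arrow_directions(self, small_sim, small_model):
        kin = fit_gamma(small_sim.spliced, small_sim.unspliced)
        nv, has = metagene_velocity(small_model, kin)
        f1 = grid_vector_field(small_model, nv, has)
        f2 = grid_vector_field(small_model, 3.7 * nv, has)
        np.testing.assert_allclose(f1.arrows, f2.arrows, atol=1e-10)

    def test_steady_state_field_vanishes(self, small_model):
        # u = gamma * s exactly -> all velocities zero -> zero field
        rng = np.random.default_rng(5)
        s = rng.uniform(1, 5, size=(small_model.n_genes, small_model.n_cells))
        sm = ExpressionMatrix(s, small_model.gene_ids, small_model.cell_ids, "spliced")
        um = ExpressionMatrix(1.5 * s, small_model.gene_ids, small_model.cell_ids, "unspliced")
        kin = fit_gamma(sm, um)
        nv, has = metagene_velocity(small_model, kin)
        field = grid_vector_field(small_model, nv, has)
        np.testing.assert_allclose(field.arrows, 0.0, atol=1e-10)


class TestAttractorsAndTrajectories:
    def _field(self, grid, arrows):
        return VelocityField(
            grid=grid,
            node_velocity=np.zeros((grid.n_nodes, 1)),
            arrows=np.asarray(arrows, dtype=float),
            has_members=np.ones(grid.n_nodes, dtype=bool),
        )

    def test_zero_field_single_peak_attractor(self):
        grid = SOMGrid(4, 4)
        field = self._field(grid, np.zeros((16, 2)))
        vals = np.zeros(16)
        vals[5] = 3.0
        att = detect_attractors(field, Portrait(grid=grid, values=vals, subject="x"))
        assert att == [5]

    def test_uniform_nonzero_field_has_no_attractors(self):
        grid = SOMGrid(4, 4)
        arrows = np.tile([0.0, 1.0], (16, 1))
        field = self._field(grid, arrows)
        vals = np.zeros(16)
        vals[5] = 3.0
        att = detect_attractors(field, Portrait(grid=grid, values=vals, subject="x"))
        assert att == []

    def test_zero_field_trajectory_stays_at_start(self):
        grid = SOMGrid(4, 4)
        field = self._field(grid, np.zeros((16, 2)))
        trajs, _ = velocity_trajectories(field, [6])
        assert trajs[0].path == [6]

    def test_constant_arrow_runs_to_boundary(self):
        grid = SOMGrid(5, 5)
        arrows = np.tile([0.0, 1.0], (25, 1))  # +col direction
        field = self._field(grid, arrows)
        start = grid.node_index(2, 0)
        trajs, _ = velocity_trajectories(field, [start], step=0.5, max_steps=100)
        path = trajs[0].path
        rows_cols = [grid.node_coord(n) for n in path]
        assert all(r == 2 for r, _ in rows_cols)
        assert rows_cols[-1][1] == 4  # reached the right boundary

    def test_two_attractor_field_basins_match_fine_step_integration(self):
        # arrows point left in the left half, right in the right half
        grid = SOMGrid(5, 8)
        arrows = np.zeros((grid.n_nodes, 2))
        attractor_l = grid.node_index(2, 0)
        attractor_r = grid.node_index(2, 7)
        for node in range(grid.n_nodes):
            r, c = grid.node_coord(node)
            if node in (attractor_l, attractor_r):
                continue
            target = attractor_l if c < 4 else attractor_r
            tr, tc = grid.node_coord(target)
            v = np.array([tr - r, tc - c], dtype=float)
            arrows[node] = v / np.linalg.norm(v)
        vals = np.zeros(grid.n_nodes)
        vals[attractor_l] = vals[attractor_r] = 5.0
        field = self._field(grid, arrows)
        detect_attractors(field, Portrait(grid=grid, values=vals, subject="x"))
        starts = list(range(grid.n_nodes))
        _, basin = velocity_trajectories(field, starts, step=0.5)
        field_fine = self._field(grid, arrows)
        field_fine.attractors = field.attractors
        _, basin_fine = velocity_trajectories(field_fine, starts, step=0.05, max_steps=5000)
        common = set(basin) & set(basin_fine)
        assert common, "expected overlapping non-watershed starts"
        agree = np.mean([basin[s] == basin_fine[s] for s in common])
        assert agree == 1.0

    def test_basin_partition_on_simulated_landscape(self, small_sim, small_model):
        from somscape.pipeline import group_mean_portraits

        kin = fit_gamma(small_sim.spliced, small_sim.unspliced)
        nv, has = metagene_velocity(small_model, kin)
        field = grid_vector_field(small_model, nv, has)
        portraits = group_mean_portraits(small_model, small_sim.annotations)
        summary = Portrait(
            grid=small_model.grid,
            values=np.max(np.column_stack([p.values for p in portraits.values()]), axis=1),
            subject="s",
        )
        detect_attractors(field, summary)
        starts = list(range(small_model.grid.n_nodes))
        _, basin = velocity_trajectories(field, starts)
        attractor_set = set(field.attractors)
        for node, att in basin.items():
            assert att in attractor_set
            assert node not in field.watershed


def test_bilinear_interpolation_matches_corners():
    grid = SOMGrid(4, 4)
    rng = np.random.default_rng(7)
    arrows = rng.normal(size=(16, 2))
    field = VelocityField(
        grid=grid,
        node_velocity=np.zeros((16, 1)),
        arrows=arrows,
        has_members=np.ones(16, dtype=bool),
    )
    for node in range(16):
        r, c = grid.node_coord(node)
        np.testing.assert_allclose(
            _bilinear_arrow(field, np.array([float(r), float(c)])), arrows[node]
        )
    mid = _bilinear_arrow(field, np.array([0.5, 0.5]))
    expected = arrows[[0, 1, 4, 5]].mean(axis=0)
    np.testing.assert_allclose(mid, expected)
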