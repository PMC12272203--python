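"""Photon diffusion FEM, adjoint Jacobian, coverage thresholding."""

import dataclasses

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from hddot.arrays import Channel
from hddot.forward import (
    DiffusionSolver,
    OpticalProperties,
    compute_jacobian,
    coverage_threshold,
    group_coverage,
    SensitivityMask,
    sensitivity_mask,
    surface_mapper,
)
from hddot.mesh import nodal_volumes
from hddot.phantoms import make_phantom

from conftest import homogeneous_properties


class SimpleOptodes:
    def __init__(self, src, det):
        self.source_positions = np.asarray(src, float)
        self.detector_positions = np.asarray(det, float)


def make_channels(opt):
    out = []
    for s in range(len(opt.source_positions)):
        for d in range(len(opt.detector_positions)):
            sep = float(
                np.linalg.norm(opt.source_positions[s] - opt.detector_positions[d])
            )
            out.append(Channel(s, d, sep))
    return out


@pytest.fixture(scope="module")
def tiny_slab():
    return make_phantom("slab", layers=(7, 2, 4), resolution=5.0, size=(40, 40, 25))


@pytest.fixture(scope="module")
def tiny_props():
    # optical scale chosen so the attenuation length is resolved by the
    # 5 mm test mesh (mu_eff * h ~ 0.5); keeps the P1 solution positive
    return homogeneous_properties(0.01, 0.4)


class TestDiffusionSolver:
    def test_system_is_spd(self, tiny_slab, tiny_props):
        solver = DiffusionSolver(tiny_slab, tiny_props, 735.0)
        K = solver.system.toarray()
        np.testing.assert_allclose(K, K.T, atol=1e-12 * np.abs(K).max())
        np.linalg.cholesky(K)  # raises if not positive definite

    def test_fluence_positive(self, tiny_slab, tiny_props):
        solver = DiffusionSolver(tiny_slab, tiny_props, 735.0)
        phi = solver.fluence([20.0, 20.0, 25.0])
        # strictly positive in the interior; discrete corner undershoot
        # is bounded by a vanishing fraction of the peak
        assert phi.min() > -1e-3 * phi.max()
        interior = np.all(
            (tiny_slab.nodes > 4.0) & (tiny_slab.nodes < np.array([36, 36, 21])),
            axis=1,
        )
        assert phi[interior].min() > 0

    def test_higher_absorption_lowers_fluence(self, tiny_slab):
        lo = homogeneous_properties(0.008, 0.4)
        hi = homogeneous_properties(0.016, 0.4)
        src = [20.0, 20.0, 25.0]
        phi_lo = DiffusionSolver(tiny_slab, lo, 735.0).fluence(src, buried=False)
        phi_hi = DiffusionSolver(tiny_slab, hi, 735.0).fluence(src, buried=False)
        pos = (phi_lo > 0) & (phi_hi > 0)
        assert pos.mean() > 0.99
        assert np.all(phi_hi[pos] < phi_lo[pos])

    def test_point_symmetric_sources_give_point_symmetric_fields(self, tiny_props):
        # the Kuhn subdivision is symmetric under inversion through the
        # box centre, so inverted sources must give inverted fields exactly
        cube = make_phantom("slab", layers=(7, 2, 4), resolution=5.0,
                            size=(40, 40, 40))
        solver = DiffusionSolver(cube, tiny_props, 735.0)
        a = solver.fluence([15.0, 20.0, 25.0], buried=False)
        b = solver.fluence([25.0, 20.0, 15.0], buried=False)
        order = np.lexsort(cube.nodes.T)
        inverted = 40.0 - cube.nodes
        order_i = np.lexsort(inverted.T)
        np.testing.assert_allclose(a[order], b[order_i], rtol=1e-9)


class TestJacobian:
    @pytest.fixture(scope="class")
    def setup(self, tiny_slab, tiny_props):
        opt = SimpleOptodes(
            [[12.0, 20.0, 25.0], [28.0, 20.0, 25.0]],
            [[20.0, 12.0, 25.0], [20.0, 28.0, 25.0]],
        )
        chans = make_channels(opt)
        J = compute_jacobian(tiny_slab, tiny_props, opt, chans, wavelengths=(735.0,))
        return opt, chans, J

    def test_reciprocity(self, tiny_slab, tiny_props, setup):
        opt, chans, J = setup
        swapped = SimpleOptodes(opt.detector_positions, opt.source_positions)
        chans_sw = [
            dataclasses.replace(c, source_index=c.detector_index,
                                detector_index=c.source_index)
            for c in chans
        ]
        J_sw = compute_jacobian(tiny_slab, tiny_props, swapped, chans_sw,
                                wavelengths=(735.0,))
        np.testing.assert_allclose(J.data, J_sw.data, rtol=1e-9)

    def test_unknown_optode_rejected(self, tiny_slab, tiny_props, setup):
        opt, _, _ = setup
        with pytest.raises(ValueError, match="unknown optode"):
            compute_jacobian(tiny_slab, tiny_props, opt, [Channel(0, 9, 10.0)],
                             wavelengths=(735.0,))

    def test_finite_difference_agreement(self, tiny_slab, tiny_props, setup):
        """Adjoint rows equal brute-force dOD/dmua to well under 1%."""
        from hddot.forward import (
            _assemble_boundary,
            _assemble_mass_nodal,
            _assemble_stiffness,
            _reflection_factor,
            _tet_gradients,
        )

        opt, chans, J = setup
        solver = DiffusionSolver(tiny_slab, tiny_props, 735.0)
        grads, vol = _tet_gradients(tiny_slab)
        S = _assemble_stiffness(tiny_slab, grads, vol, solver.kappa_e)
        B = _assemble_boundary(tiny_slab, solver.scalp, 1 / (2 * _reflection_factor(1.4)))
        src_loads = np.stack([solver.load_vector(p) for p in opt.source_positions], axis=1)
        det_loads = np.stack([solver.load_vector(p) for p in opt.detector_positions], axis=1)
        phi0 = solver.solve(src_loads)
        eps = 1e-6
        rng = np.random.default_rng(1)
        nodes = rng.choice(tiny_slab.n_nodes, 25, replace=False)
        worst = 0.0
        for nidx in nodes:
            mua = solver.mua_nodal.copy()
            mua[nidx] += eps
            K2 = S + _assemble_mass_nodal(tiny_slab, vol, mua) + B
            phi2 = spla.splu(K2.tocsc()).solve(src_loads)
            for row, ch in enumerate(chans):
                s, d = ch.source_index, ch.detector_index
                a0 = det_loads[:, d] @ phi0[:, s]
                a2 = det_loads[:, d] @ phi2[:, s]
                fd = -(np.log(a2) - np.log(a0)) / eps
                scale = np.abs(J.data[row]).max()
                if abs(fd) > 1e-6 * scale:
                    worst = max(worst, abs(J.data[row, nidx] - fd) / abs(fd))
        assert worst < 0.01

    def test_sensitivity_decays_with_shrinking_separation_at_depth(
        self, tiny_slab, tiny_props
    ):
        """Banana shape: deep sensitivity drops as separation shrinks."""
        depth_pt = np.array([20.0, 20.0, 25.0 - 12.0])
        node = int(np.argmin(np.linalg.norm(tiny_slab.nodes - depth_pt, axis=1)))
        vals = []
        for half in (5.0, 10.0, 15.0):
            opt = SimpleOptodes([[20.0 - half, 20.0, 25.0]], [[20.0 + half, 20.0, 25.0]])
            J = compute_jacobian(tiny_slab, tiny_props, opt, make_channels(opt),
                                 wavelengths=(735.0,))
            vals.append(J.data[0, node])
        assert vals[0] < vals[1] < vals[2]


class TestCoverage:
    def test_threshold_formula(self):
        # independent hand evaluation: ln(1.01) / (0.0019 * 1000 / 2)
        expected = np.log(1.01) / (0.0019 * 1000.0 / 2.0)
        assert coverage_threshold(2.0, delta_mua=0.0019) == pytest.approx(expected)

    def test_zero_pthresh_gives_zero(self):
        assert coverage_threshold(2.0, delta_mua=0.0019, pthresh=0.0) == 0.0

    def test_threshold_proportional_to_volume(self):
        a = coverage_threshold(2.0, delta_mua=0.0019)
        b = coverage_threshold(4.0, delta_mua=0.0019)
        assert b == pytest.approx(2 * a)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            coverage_threshold(0.0, delta_mua=0.0019)

    @pytest.fixture(scope="class")
    def masked(self, tiny_slab, tiny_props):
        opt = SimpleOptodes(
            [[14.0, 20.0, 25.0], [20.0, 14.0, 25.0]],
            [[26.0, 20.0, 25.0], [20.0, 26.0, 25.0]],
        )
        J = compute_jacobian(tiny_slab, tiny_props, opt, make_channels(opt),
                             wavelengths=(735.0,))
        cortex = tiny_slab.cortical_surface()
        smap = surface_mapper(cortex, tiny_slab, radius=3.0)
        return J, smap

    def test_threshold_above_max_gives_empty_mask(self, masked):
        J, smap = masked
        mask = sensitivity_mask(J, 10 * np.abs(J.data).max(), smap)
        assert not mask.covered.any()

    def test_zero_threshold_marks_positive_sensitivity(self, masked):
        J, smap = masked
        mask = sensitivity_mask(J, 0.0, smap)
        surf = smap @ np.abs(J.data).T
        np.testing.assert_array_equal(mask.covered, (surf > 0).any(axis=1))

    def test_mask_monotone_in_threshold(self, masked):
        J, smap = masked
        lo = sensitivity_mask(J, 1e-4, smap).covered
        hi = sensitivity_mask(J, 1e-2, smap).covered
        assert np.all(~hi | lo)  # higher threshold is a subset

    def test_band_nesting(self, masked):
        J, smap = masked
        thr = 1e-4
        short = np.flatnonzero(J.separation <= 15.0)
        all40 = np.flatnonzero(J.separation <= 40.0)
        m_short = sensitivity_mask(J.select(short), thr, smap).covered
        m_40 = sensitivity_mask(J.select(all40), thr, smap).covered
        assert np.all(~m_short | m_40)


class TestGroupCoverage:
    def _mask(self, bits):
        return SensitivityMask(np.asarray(bits, bool))

    def test_identical_masks(self):
        m = self._mask([1, 0, 1, 1])
        count, inc = group_coverage([m] * 16)
        np.testing.assert_array_equal(count, [16, 0, 16, 16])
        np.testing.assert_array_equal(inc, m.covered)

    def test_75_percent_boundary_inclusive(self):
        masks = [self._mask([1]) for _ in range(12)] + [self._mask([0]) for _ in range(4)]
        count, inc = group_coverage(masks)
        assert count[0] == 12 and inc[0]  # 12/16 = 75% included

    def test_below_boundary_excluded(self):
        masks = [self._mask([1]) for _ in range(11)] + [self._mask([0]) for _ in range(5)]
        count, inc = group_coverage(masks)
        assert count[0] == 11 and not inc[0]  # 68.75% excluded

    def test_mismatched_surfaces_rejected(self):
        with pytest.raises(ValueError, match="different"):
            group_coverage([self._mask([1, 0]), self._mask([1, 0, 1])])
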