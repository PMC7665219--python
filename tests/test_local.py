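"""Locally varying correction: tiling, padding, reciprocity, stitching."""

import warnings

import numpy as np
import pytest

from lsrmm import forward, local, matrix, metrics, solver
from lsrmm._fft import negate_k
from lsrmm.forward import InvalidConfiguration


def _zero_stack(opt):
    scan = np.arange(0, opt.grid_size, opt.scan_step_px)
    data = np.zeros((scan.size, scan.size, opt.grid_size, opt.grid_size), dtype=complex)
    return forward.FieldStack(data=data, optics=opt, scan_y_px=scan, scan_x_px=scan)


@pytest.fixture(scope="module")
def global_screen_stack(optics64):
    """Shift-invariant (single-screen) simulation for consistency checks."""
    amp = np.clip(0.3 + 0.7 * forward.make_filaments(10, 2.0, 3, side_px=64), 0, 1)
    rng = np.random.default_rng(9)
    obj = forward.ObjectMap(amp * np.exp(1j * rng.uniform(-np.pi, np.pi, amp.shape)), optics64)
    phi_i = forward.make_pupil_phase(optics64, "bandlimited_speckle", {"n_modes": 250}, seed=21)
    phi_o = forward.PupilPhase(negate_k(phi_i.phase), phi_i.dk, phi_i.mask, "output")
    stack = forward.simulate_scan(obj, phi_i, phi_o)
    return {"stack": stack, "phi_i": phi_i, "phi_o": phi_o}


class TestTiling:
    def test_single_tile_when_subregion_is_foi(self, optics64):
        st = _zero_stack(optics64)
        tiling = local.tile_foi(st, optics64.extent)
        assert len(tiling.tiles) == 1
        assert tiling.tiles[0].core == (0, 32, 0, 32)

    def test_tile_count_matches_ratio(self, optics64):
        # FOI/subregion = 15 -> 15 x 15 tiles
        st = _zero_stack(optics64)
        tiling = local.tile_foi(st, optics64.extent / 15)
        assert tiling.grid == (16, 16) or tiling.grid == (15, 15)
        # cores cover the scan grid exactly once
        cover = np.zeros((32, 32), dtype=int)
        for t in tiling.tiles:
            ay0, ay1, ax0, ax1 = t.core
            cover[ay0:ay1, ax0:ax1] += 1
        assert np.all(cover == 1)

    def test_margins_clipped_at_boundary(self, optics64):
        st = _zero_stack(optics64)
        tiling = local.tile_foi(st, 7.2, margin=0.9)  # 2 scan-px margin
        t00 = tiling.tiles[0]
        assert t00.ext == (0, 18, 0, 18)
        t11 = [t for t in tiling.tiles if t.core == (16, 32, 16, 32)][0]
        assert t11.ext == (14, 32, 14, 32)

    def test_rejects_bad_parameters(self, optics64):
        st = _zero_stack(optics64)
        with pytest.raises(InvalidConfiguration):
            local.tile_foi(st, 0.0)
        with pytest.raises(InvalidConfiguration):
            local.tile_foi(st, 5.0, margin=-1.0)


class TestSubMatrix:
    def test_entries_match_stack_samples(self, optics64):
        rng = np.random.default_rng(5)
        st = _zero_stack(optics64)
        st.data[:] = rng.standard_normal(st.data.shape) + 1j * rng.standard_normal(st.data.shape)
        lab = forward.FieldStack(
            data=st.data, optics=st.optics, scan_y_px=st.scan_y_px,
            scan_x_px=st.scan_x_px, frame="lab",
        )
        tiling = local.tile_foi(lab, 7.2)
        tile = tiling.tiles[1]
        rsub = local.build_sub_matrix(lab, tile)
        ey0, ey1, ex0, ex1 = tile.ext
        n = optics64.grid_size
        # spot-check index bookkeeping
        for (row, col) in [(0, 0), (5, 3), (rsub.data.shape[0] - 1, rsub.data.shape[1] - 1)]:
            wy = tile.win_y_px[row // tile.win_x_px.size] % n
            wx = tile.win_x_px[row % tile.win_x_px.size] % n
            a = ey0 + col // (ex1 - ex0)
            b = ex0 + col % (ex1 - ex0)
            assert rsub.data[row, col] == lab.data[a, b, wy, wx]

    def test_single_tile_reduces_to_assemble(self, optics64):
        rng = np.random.default_rng(6)
        st = _zero_stack(optics64)
        st.data[:] = rng.standard_normal(st.data.shape)
        lab = forward.FieldStack(
            data=st.data, optics=st.optics, scan_y_px=st.scan_y_px,
            scan_x_px=st.scan_x_px, frame="lab",
        )
        tiling = local.tile_foi(lab, optics64.extent)
        rsub = local.build_sub_matrix(lab, tiling.tiles[0])
        ref = matrix.crop_to_scan_grid(matrix.assemble_matrix(lab))
        assert np.allclose(rsub.data, ref.data)

    def test_input_mode_count_formula(self, optics64):
        """N_i equals (FOI_sub / delta_d)^2 for diffraction-limited scanning."""
        st = _zero_stack(optics64)
        tiling = local.tile_foi(st, 7.2)
        n_i = tiling.tiles[0].n_i
        assert n_i == round((7.2 / optics64.delta_d) ** 2)


class TestPadToSquare:
    def test_toy_padding_positions(self, optics16):
        scan = np.arange(0, 16, 2)
        rm = matrix.ReflectionMatrix(
            data=np.arange(64 * 4, dtype=complex).reshape(64, 4),
            optics=optics16,
            out_y_px=scan, out_x_px=scan,
            in_y_px=scan[:2], in_x_px=scan[:2],
        )
        sq = local.pad_to_square(rm)
        assert sq.data.shape == (64, 64)
        assert np.linalg.norm(sq.data) == pytest.approx(np.linalg.norm(rm.data))
        # real columns sit at the window positions of their scan coordinates
        r4 = sq.as4d()
        assert np.allclose(r4[:, :, 0, 0].ravel(), rm.data[:, 0])
        assert np.allclose(r4[:, :, 0, 1].ravel(), rm.data[:, 1])
        # all other columns zero
        assert np.linalg.norm(r4[:, :, 2:, :]) == 0

    def test_square_input_is_identity(self, optics16):
        rng = np.random.default_rng(1)
        scan = np.arange(0, 16, 2)
        rm = matrix.ReflectionMatrix(
            data=rng.standard_normal((64, 64)), optics=optics16,
            out_y_px=scan, out_x_px=scan, in_y_px=scan, in_x_px=scan,
        )
        assert local.pad_to_square(rm) is rm

    def test_wide_matrix_rejected(self, optics16):
        scan = np.arange(0, 16, 2)
        rm = matrix.ReflectionMatrix(
            data=np.zeros((4, 64)), optics=optics16,
            out_y_px=scan[:2], out_x_px=scan[:2], in_y_px=scan, in_x_px=scan,
        )
        with pytest.raises(InvalidConfiguration):
            local.pad_to_square(rm)

    def test_zero_columns_do_not_contribute_to_spectrum(self, optics16):
        """The CLASS spectrum ignores padded columns entirely."""
        rng = np.random.default_rng(2)
        scan = np.arange(0, 16, 2)
        rm = matrix.ReflectionMatrix(
            data=rng.standard_normal((64, 16)) + 1j * rng.standard_normal((64, 16)),
            optics=optics16,
            out_y_px=scan, out_x_px=scan, in_y_px=scan[:4], in_x_px=scan[:4],
        )
        sq = local.pad_to_square(rm)
        sm = matrix.to_spectral(sq)
        spec = solver.class_spectrum(sm)
        # oracle: sum the (space-domain) columns' spectra by brute force in k
        sm4 = sm.as4d()
        ny = 8
        brute = np.zeros((15, 15), dtype=complex)
        for a in range(ny):
            for b in range(ny):
                brute[ny - 1 - a : 2 * ny - 1 - a, ny - 1 - b : 2 * ny - 1 - b] += sm4[:, :, a, b]
        assert np.allclose(spec, brute)


class TestLocalClass:
    def test_one_tile_two_sided_matches_global_solver(self, global_screen_stack):
        """Single tile with FOI = FOD reduces to the global CLASS result."""
        st = global_screen_stack["stack"]
        tiling = local.tile_foi(st, st.optics.extent)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loc = local.run_local_class(st, tiling, max_iter=40, reciprocity=False)
            lab = matrix.descan_to_lab(st)
            ref = solver.run_class(
                matrix.to_spectral(matrix.crop_to_scan_grid(matrix.assemble_matrix(lab))),
                max_iter=40,
            )
        tr = loc.tiles[0]
        mask = tr.phi_o.mask
        d = np.angle(np.exp(1j * (tr.phi_o.phase - ref.phi_o.phase)))[mask]
        assert np.sqrt(np.mean(d**2)) < 1e-6

    def test_global_screen_all_tiles_agree(self, global_screen_stack):
        """A shift-invariant screen yields the same map in every tile."""
        st = global_screen_stack["stack"]
        tiling = local.tile_foi(st, 7.2, margin=1.8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = local.run_local_class(st, tiling, max_iter=50)
        maps = [t.phi_o for t in res.tiles]
        mask = maps[0].mask
        for other in maps[1:]:
            ag = metrics.phase_agreement(maps[0].phase, other.phase, mask)
            assert ag["rms_rad"] < 0.15

    def test_tile_maps_span_full_fod_mode_set(self, global_screen_stack):
        """Pupil mode count per tile stays at the FOD capacity."""
        st = global_screen_stack["stack"]
        opt = st.optics
        tiling = local.tile_foi(st, 7.2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = local.run_local_class(st, tiling, max_iter=5)
        fod_side = st.frame_shape[0] * opt.pixel_pitch
        plan = forward.plan_acquisition(opt, 7.2, fod_side, 40000)
        n_modes_analytic = local.count_na_modes(fod_side, opt)
        assert abs(n_modes_analytic - plan.n_modes) / plan.n_modes < 0.05
        for t in res.tiles:
            # every tile's map spans the FOD capacity (to lattice rounding)
            assert abs(int(t.phi_o.mask.sum()) - plan.n_modes) / plan.n_modes < 0.05


class TestStitch:
    def _tile_result(self, tile, value):
        ey0, ey1, ex0, ex1 = tile.ext
        img = np.full((ey1 - ey0, ex1 - ex0), float(value))
        return local.TileResult(
            tile=tile, phi_o=None, phi_i=None, image=img, log=[],
            converged=True, objective_gain=1.0,
        )

    def test_single_tile_identity(self, optics64):
        st = _zero_stack(optics64)
        tiling = local.tile_foi(st, optics64.extent)
        out = local.stitch([self._tile_result(tiling.tiles[0], 3.5)], tiling, (32, 32))
        assert np.allclose(out, 3.5)

    def test_constant_tiles_give_constant_output(self, optics64):
        st = _zero_stack(optics64)
        tiling = local.tile_foi(st, 3.6, margin=0.9)
        tiles = [self._tile_result(t, 2.0) for t in tiling.tiles]
        out = local.stitch(tiles, tiling, (32, 32))
        assert np.allclose(out, 2.0)

    def test_weight_partition_of_unity(self, optics64):
        """Unit tiles stitch to exactly one everywhere (weights normalised)."""
        st = _zero_stack(optics64)
        tiling = local.tile_foi(st, 7.2, margin=1.8)
        tiles = [self._tile_result(t, 1.0) for t in tiling.tiles]
        out = local.stitch(tiles, tiling, (32, 32))
        assert np.allclose(out, 1.0, atol=1e-12)


class TestIsoplanaticSearch:
    def test_single_candidate_warns(self, global_screen_stack):
        st = global_screen_stack["stack"]
        with pytest.warns(RuntimeWarning):
            est = local.estimate_isoplanatic_size(st, [14.4], max_iter=3)
        assert est.side == 14.4

    def test_shift_invariant_prefers_largest(self, global_screen_stack):
        """With one global screen the largest candidate wins (or plateaus)."""
        st = global_screen_stack["stack"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = local.estimate_isoplanatic_size(st, [7.2, 14.4], max_iter=40)
        assert est.side == 14.4
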