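"""Locally varying high-order aberration correction.

Through a strongly layered medium the pupil aberration changes across the
field of illumination (FOI); a single CLASS correction then averages over
isoplanatic patches and fails.  This module tiles the FOI into subregions and
corrects each independently — but, crucially, without giving up pupil
resolution: the output window of every tile keeps the full field of detection
(FOD), so the per-tile reflection matrix is an N_o x N_i *rectangular* matrix
(N_o set by the window of side sqrt(FOD) + sqrt(FOI), N_i by the subregion).
Zero columns are appended at window pixels that are not scan positions to
square the matrix; the spectral grid spacing is then
``δk = 2π / (sqrt(FOD) + sqrt(FOI))`` on both sides, and the correction spans
all N_c modes supported by the FOD even for patches only a few µm across.

By optical reciprocity the detection and illumination pupils of one medium
satisfy ``phi_i(k) = phi_o(-k)``; the per-tile iteration therefore estimates
the output phase from all rows (which are never padded) and mirrors it onto
the input side, avoiding the poorly conditioned column-wise estimate on few
real columns.  Corrected tiles are blended with raised-cosine weights over
their overlap margins; the isoplanatic patch size is found by sweeping the
subregion side and picking the largest side whose corrected image intensity
is within tolerance of the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fft import negate_k
from .forward import FieldStack, InvalidConfiguration, PupilPhase
from .matrix import (
    ReflectionMatrix,
    descan_to_lab,
    from_spectral,
    to_spectral,
)
from .solver import (
    _masked_rms,
    apply_step,
    class_spectrum,
    input_phase_step,
    output_phase_step,
)


@dataclass
class Tile:
    """One subregion: core scan-index ranges, margin-expanded ranges, and the
    enlarged output window (unwrapped scan-pitch pixel coordinates)."""

    core: tuple[int, int, int, int]  # ay0, ay1, ax0, ax1 (scan indices)
    ext: tuple[int, int, int, int]  # with overlap margin, clipped
    win_y_px: np.ndarray  # output-window lattice, absolute px (unwrapped)
    win_x_px: np.ndarray

    @property
    def n_i(self) -> int:
        ey0, ey1, ex0, ex1 = self.ext
        return (ey1 - ey0) * (ex1 - ex0)

    @property
    def n_o(self) -> int:
        return self.win_y_px.size * self.win_x_px.size


@dataclass
class Tiling:
    subregion_side: float  # µm
    margin: float  # µm
    tiles: list = field(default_factory=list)
    grid: tuple[int, int] = (1, 1)  # tiles per (y, x)


def tile_foi(
    stack: FieldStack, subregion_side: float, margin: float = 0.0
) -> Tiling:
    """Divide the scan grid into subregions with symmetric overlap margins.

    ``subregion_side`` and ``margin`` are in µm; boundary tiles are clipped.
    Each tile's output window extends the margin-expanded subregion by half
    the detection window on every side (total side sqrt(FOD)+sqrt(FOI)),
    capped at the periodic grid extent.
    """
    opt = stack.optics
    step = opt.scan_step_px
    step_um = step * opt.pixel_pitch
    sy, sx = stack.data.shape[:2]
    if subregion_side <= 0:
        raise InvalidConfiguration("subregion_side must be positive")
    if margin < 0:
        raise InvalidConfiguration("margin must be >= 0")
    core_n = max(1, int(round(subregion_side / step_um)))
    core_n = min(core_n, max(sy, sx))
    m = int(round(margin / step_um))
    fod_px = stack.frame_shape[0]
    w_ext = (fod_px // 2) // step  # window margin in scan-pitch samples

    tiles: list[Tile] = []
    n_ty = (sy + core_n - 1) // core_n
    n_tx = (sx + core_n - 1) // core_n
    for ty in range(n_ty):
        for tx in range(n_tx):
            ay0, ay1 = ty * core_n, min((ty + 1) * core_n, sy)
            ax0, ax1 = tx * core_n, min((tx + 1) * core_n, sx)
            ey0, ey1 = max(0, ay0 - m), min(sy, ay1 + m)
            ex0, ex1 = max(0, ax0 - m), min(sx, ax1 + m)

            def _window(p0: int, p1: int, axis_px: np.ndarray, n_scan: int) -> np.ndarray:
                count = (p1 - p0) + 2 * w_ext
                if count >= n_scan:
                    return np.asarray(axis_px, dtype=int)
                start = int(axis_px[p0]) - w_ext * step
                return start + step * np.arange(count)

            tiles.append(
                Tile(
                    core=(ay0, ay1, ax0, ax1),
                    ext=(ey0, ey1, ex0, ex1),
                    win_y_px=_window(ey0, ey1, stack.scan_y_px, sy),
                    win_x_px=_window(ex0, ex1, stack.scan_x_px, sx),
                )
            )
    return Tiling(
        subregion_side=subregion_side, margin=margin, tiles=tiles,
        grid=(n_ty, n_tx),
    )


def build_sub_matrix(stack: FieldStack, tile: Tile) -> ReflectionMatrix:
    """Rectangular N_o x N_i matrix for one tile from a lab-frame stack.

    Columns are the tile's (margin-expanded) scan positions; rows are the
    output-window lattice at scan pitch; window coordinates index the
    periodic grid modulo its size, and unmeasured pixels are zero already.
    """
    if stack.frame != "lab":
        raise InvalidConfiguration("build_sub_matrix expects a lab-frame stack")
    n = stack.optics.grid_size
    ey0, ey1, ex0, ex1 = tile.ext
    wy = np.mod(tile.win_y_px, n)
    wx = np.mod(tile.win_x_px, n)
    frames = stack.data[ey0:ey1, ex0:ex1]  # (ty, tx, n, n)
    sub = frames[:, :, wy[:, None], wx[None, :]]  # (ty, tx, wy, wx)
    n_i = (ey1 - ey0) * (ex1 - ex0)
    data = sub.reshape(n_i, tile.n_o).T.copy()
    return ReflectionMatrix(
        data=data, optics=stack.optics,
        out_y_px=tile.win_y_px, out_x_px=tile.win_x_px,
        in_y_px=stack.scan_y_px[ey0:ey1], in_x_px=stack.scan_x_px[ex0:ex1],
        meta={"tile_core": tile.core, "tile_ext": tile.ext},
    )


def pad_to_square(rm: ReflectionMatrix) -> ReflectionMatrix:
    """Append zero columns so the input lattice matches the output window.

    Real columns keep their spatial registration inside the window grid; the
    added columns correspond to window pixels that were never illuminated and
    contribute nothing anywhere (Frobenius norm unchanged).
    """
    n_o, n_i = rm.data.shape
    if n_o < n_i:
        raise InvalidConfiguration("pad_to_square needs N_o >= N_i")
    if rm.is_square_lattice():
        return rm
    pos_y = {int(v): i for i, v in enumerate(rm.out_y_px)}
    pos_x = {int(v): i for i, v in enumerate(rm.out_x_px)}
    try:
        iy = [pos_y[int(v)] for v in rm.in_y_px]
        ix = [pos_x[int(v)] for v in rm.in_x_px]
    except KeyError:
        raise InvalidConfiguration(
            "scan positions must lie inside the output window"
        ) from None
    ny, nx = rm.out_shape
    out4 = np.zeros((ny, nx, ny, nx), dtype=rm.data.dtype)
    r4 = rm.as4d()
    for a, ia in enumerate(iy):
        for b, ib in enumerate(ix):
            out4[:, :, ia, ib] = r4[:, :, a, b]
    return ReflectionMatrix(
        data=out4.reshape(n_o, n_o), optics=rm.optics,
        out_y_px=rm.out_y_px, out_x_px=rm.out_x_px,
        in_y_px=rm.out_y_px, in_x_px=rm.out_x_px, meta=dict(rm.meta),
    )


@dataclass
class TileResult:
    tile: Tile
    phi_o: PupilPhase  # estimated detection aberration, window k-grid
    phi_i: PupilPhase
    image: np.ndarray  # corrected confocal intensity over the ext region
    log: list
    converged: bool
    objective_gain: float  # final / initial confocal intensity


@dataclass
class LocalResult:
    tiling: Tiling
    tiles: list
    stitched: np.ndarray  # corrected image over the full scan grid

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.stitched))


def _correct_tile(
    stack_lab: FieldStack,
    tile: Tile,
    tol: float,
    max_iter: int,
    reciprocity: bool,
) -> TileResult:
    rsub = build_sub_matrix(stack_lab, tile)
    sm = to_spectral(pad_to_square(rsub))
    mask = sm.mask_out
    acc_o = np.zeros(sm.out_shape)
    acc_i = np.zeros(sm.out_shape)
    log: list[dict] = []
    converged = False
    spectrum = class_spectrum(sm)
    obj0 = float(np.sum(np.abs(spectrum) ** 2))
    prev_objective = obj0
    for n in range(1, max_iter + 1):
        if reciprocity:
            # single output-side estimate, mirrored onto the input side
            phi_o = output_phase_step(sm, spectrum)
            phi_i = np.where(mask, negate_k(phi_o), 0.0)
            sm = apply_step(sm, phi_i, phi_o)
            acc_o += phi_o
            acc_i += phi_i
            spectrum = class_spectrum(sm)
        else:
            # sequential two-sided update, identical to the global solver
            phi_i = input_phase_step(sm, spectrum)
            sm = apply_step(sm, phi_i, np.zeros_like(phi_i))
            acc_i += phi_i
            spectrum = class_spectrum(sm)
            phi_o = output_phase_step(sm, spectrum)
            sm = apply_step(sm, np.zeros_like(phi_o), phi_o)
            acc_o += phi_o
            spectrum = class_spectrum(sm)
        objective = float(np.sum(np.abs(spectrum) ** 2))
        rms_o = _masked_rms(phi_o, mask)
        rms_i = _masked_rms(phi_i, mask)
        log.append({"n": n, "objective": objective, "rms_o": rms_o, "rms_i": rms_i})
        # as in the global solver: increments must stall together with the
        # objective before the iteration is declared converged
        stalled = abs(objective - prev_objective) < 1e-6 * max(prev_objective, 1e-300)
        prev_objective = objective
        if rms_o < tol and rms_i < tol and stalled:
            converged = True
            break

    # corrected confocal values on the tile's real (illuminated) columns
    rc = from_spectral(sm)
    r4 = rc.as4d()
    ey0, ey1, ex0, ex1 = tile.ext
    col_y = stack_lab.scan_y_px[ey0:ey1]
    col_x = stack_lab.scan_x_px[ex0:ex1]
    pos_y = {int(v): i for i, v in enumerate(rc.out_y_px)}
    pos_x = {int(v): i for i, v in enumerate(rc.out_x_px)}
    img = np.empty((col_y.size, col_x.size))
    for a, vy in enumerate(col_y):
        for b, vx in enumerate(col_x):
            ia, ib = pos_y[int(vy)], pos_x[int(vx)]
            img[a, b] = np.abs(r4[ia, ib, ia, ib]) ** 2
    # spectral correction of a column-selected matrix dilutes the corrected
    # diagonal by the illuminated-column fraction N_i/N_o (the zero columns
    # contribute nothing to the input-side basis change); renormalise so
    # tiles of different sizes share one confocal intensity scale
    img /= tile.n_i / tile.n_o

    dk = sm.dk_out[0]

    def _report(acc: np.ndarray, side: str) -> PupilPhase:
        from ._fft import wrap_phase

        est = np.where(mask, -acc, 0.0)
        piston = np.angle(np.mean(np.exp(1j * est[mask])))
        return PupilPhase(
            phase=np.where(mask, wrap_phase(est - piston), 0.0),
            dk=dk, mask=mask, side=side,
        )

    objective = log[-1]["objective"] if log else obj0
    return TileResult(
        tile=tile,
        phi_o=_report(acc_o, "output"),
        phi_i=_report(acc_i, "input"),
        image=img,
        log=log,
        converged=converged,
        objective_gain=objective / obj0 if obj0 > 0 else float("nan"),
    )


def run_local_class(
    stack: FieldStack,
    tiling: Tiling,
    tol: float = 0.01,
    max_iter: int = 50,
    reciprocity: bool = True,
) -> LocalResult:
    """Correct every tile independently and stitch the corrected images."""
    stack_lab = stack if stack.frame == "lab" else descan_to_lab(stack)
    results = [
        _correct_tile(stack_lab, t, tol, max_iter, reciprocity)
        for t in tiling.tiles
    ]
    for r in results:
        if not r.converged:
            warnings.warn(
                f"tile {r.tile.core} did not converge", RuntimeWarning
            )
    stitched = stitch(results, tiling, stack.data.shape[:2])
    return LocalResult(tiling=tiling, tiles=results, stitched=stitched)


def _taper_profile(core0: int, core1: int, ext0: int, ext1: int) -> np.ndarray:
    """Raised-cosine weight over an extended range: 1 on the core, tapering
    across the overlap margin."""
    w = np.ones(ext1 - ext0)
    m_left = core0 - ext0
    for j in range(m_left):
        d = m_left - j  # 1..m at the outermost pixel
        w[j] = np.cos(np.pi / 2.0 * (d - 0.5) / m_left) ** 2
    m_right = ext1 - core1
    for j in range(m_right):
        d = j + 1
        w[ext1 - ext0 - m_right + j] = np.cos(np.pi / 2.0 * (d - 0.5) / m_right) ** 2
    return w


def stitch(
    tiles: list, tiling: Tiling, scan_shape: tuple[int, int]
) -> np.ndarray:
    """Blend per-tile corrected images with normalised raised-cosine weights.

    The normalisation makes the effective weights sum to one everywhere; with
    zero margin this reduces to abutting the tile cores.
    """
    num = np.zeros(scan_shape)
    den = np.zeros(scan_shape)
    for tr in tiles:
        t = tr.tile
        ay0, ay1, ax0, ax1 = t.core
        ey0, ey1, ex0, ex1 = t.ext
        wy = _taper_profile(ay0, ay1, ey0, ey1)
        wx = _taper_profile(ax0, ax1, ex0, ex1)
        w = wy[:, None] * wx[None, :]
        num[ey0:ey1, ex0:ex1] += w * tr.image
        den[ey0:ey1, ex0:ex1] += w
    if np.any(den == 0):
        raise InvalidConfiguration("tiles do not cover the scan grid")
    return num / den


@dataclass
class PatchSizeEstimate:
    side: float  # µm
    plateau: bool
    sweep: list  # (side_um, mean corrected intensity)
    results: dict  # side -> LocalResult


def estimate_isoplanatic_size(
    stack: FieldStack,
    candidate_sides: list,
    margin: float = 0.0,
    tol: float = 0.01,
    max_iter: int = 30,
    rel_tol: float = 0.03,
    reciprocity: bool = True,
) -> PatchSizeEstimate:
    """Sweep subregion sides; return the largest within tolerance of the
    intensity maximum.

    The corrected-image intensity saturates once the subregion is no larger
    than the isoplanatic patch; among near-maximal candidates the largest is
    preferred (flagging the plateau).  ``rel_tol`` absorbs the few-percent
    size-dependent residue of the padded-correction intensity normalisation.
    A single candidate is returned as-is with a warning.
    """
    if len(candidate_sides) < 1:
        raise InvalidConfiguration("need at least one candidate side")
    if len(candidate_sides) == 1:
        warnings.warn("single candidate: returned as-is", RuntimeWarning)
    results: dict = {}
    sweep = []
    for side in candidate_sides:
        tiling = tile_foi(stack, side, margin)
        res = run_local_class(stack, tiling, tol=tol, max_iter=max_iter,
                              reciprocity=reciprocity)
        results[side] = res
        sweep.append((float(side), res.mean_intensity))
    best_val = max(v for _, v in sweep)
    near = [s for s, v in sweep if v >= (1.0 - rel_tol) * best_val]
    plateau = len(near) > 1
    return PatchSizeEstimate(
        side=float(max(near)), plateau=plateau, sweep=sweep, results=results
    )


def count_na_modes(fod_side: float, optics) -> int:
    """Number of pupil k-grid points (spacing 2π/√FOD) inside the NA disk.

    Agrees with the analytic planner N_c = π (√FOD / 2 δ_d)² up to lattice
    rounding; used to assert that per-tile maps keep the full FOD mode set.
    """
    dk = 2.0 * np.pi / fod_side
    m = int(np.ceil(optics.k_na / dk)) + 1
    idx = np.arange(-m, m + 1)
    kk = idx * dk
    kyg, kxg = np.meshgrid(kk, kk, indexing="ij")
    return int(np.sum(kyg**2 + kxg**2 < optics.k_na**2))
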