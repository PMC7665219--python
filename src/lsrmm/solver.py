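"""CLASS: closed-loop accumulation of single scattering.

Within an isoplanatic patch the spectral reflection matrix factorises as
``R~(k_o; k_i) = exp(i phi_o(k_o)) O~(k_o - k_i) exp(i phi_i(k_i)) + M~``:
the object couples only to the momentum difference ``Δk = k_o - k_i``, while
the two pupil aberrations act as diagonal phase factors.  CLASS exploits this
by summing matrix entries along fixed Δk (anti-diagonals),

    R_CLASS(Δk) = sum_{k_i} R~(k_i + Δk; k_i),

where single-scattered contributions add coherently once the pupil phases are
compensated, and multiple-scattering speckle averages out.  Each iteration
estimates phase increments by correlating columns (rows) against the CLASS
spectrum,

    phi_i_step(k_i) = arg sum_{Δk} R~(Δk; k_i)* R_CLASS(Δk),
    phi_o_step(k_o) = arg sum_{Δk} R~(k_o; Δk)* R_CLASS(-Δk),

applies them multiplicatively, and recomputes the spectrum; the increments
converge to zero and their running sums are the (negated) pupil aberrations.
The iteration maximises the total intensity of the reconstructed confocal
image.  All comparisons against ground truth are made modulo piston and
linear tilt, which are fundamental degeneracies (they trade against the
object's global phase and position).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fft import cidft2, wrap_phase
from .forward import InvalidConfiguration, PupilPhase
from .matrix import ReflectionMatrix, SpectralMatrix, from_spectral


def _require_square(sm: SpectralMatrix) -> None:
    if sm.out_shape != sm.in_shape or not (
        np.array_equal(sm.out_y_px, sm.in_y_px)
        and np.array_equal(sm.out_x_px, sm.in_x_px)
    ):
        raise InvalidConfiguration("CLASS needs a square spectral matrix on a shared k-grid")


def class_spectrum(sm: SpectralMatrix) -> np.ndarray:
    """Anti-diagonal sums R_CLASS(Δk) over the full difference set.

    Returns a (2 Ny - 1, 2 Nx - 1) array; Δk = 0 sits at index
    (Ny - 1, Nx - 1).
    """
    _require_square(sm)
    r4 = sm.as4d()
    ny, nx = sm.in_shape
    out = np.zeros((2 * ny - 1, 2 * nx - 1), dtype=complex)
    for a in range(ny):
        for b in range(nx):
            out[ny - 1 - a : 2 * ny - 1 - a, nx - 1 - b : 2 * nx - 1 - b] += r4[:, :, a, b]
    return out


def input_phase_step(sm: SpectralMatrix, spectrum: np.ndarray) -> np.ndarray:
    """Phase increment per k_i: arg of the column / CLASS-spectrum correlation.

    ``arg(0)`` is taken as 0 (dark or masked-out modes are a no-op); modes
    outside the NA disk are never updated.
    """
    _require_square(sm)
    r4 = sm.as4d()
    ny, nx = sm.in_shape
    phi = np.zeros((ny, nx))
    mask = sm.mask_in
    for a in range(ny):
        for b in range(nx):
            if not mask[a, b]:
                continue
            block = spectrum[ny - 1 - a : 2 * ny - 1 - a, nx - 1 - b : 2 * nx - 1 - b]
            phi[a, b] = np.angle(np.sum(np.conj(r4[:, :, a, b]) * block))
    return phi


def output_phase_step(sm: SpectralMatrix, spectrum: np.ndarray) -> np.ndarray:
    """Phase increment per k_o (row-wise correlation against the spectrum).

    Rows are re-indexed by the momentum difference with the transpose
    convention (Δk = k_i - k_o), under which the correlation pairs every
    entry with the CLASS spectrum at its own output-minus-input difference:

        phi_o(k_o) = arg sum_{k_i} R~(k_o; k_i)* R_CLASS(k_o - k_i).

    Like the input step, each term then carries |O~(Δk)|^2 — no object phase
    — so the estimator works for complex (diffuse) reflectance too.
    """
    _require_square(sm)
    r4 = sm.as4d()
    ny, nx = sm.out_shape
    phi = np.zeros((ny, nx))
    mask = sm.mask_out
    for c in range(ny):
        for d in range(nx):
            if not mask[c, d]:
                continue
            # C at k_o - k_i for k_i over the grid: reversed window slice
            block = spectrum[c : c + ny, d : d + nx][::-1, ::-1]
            phi[c, d] = np.angle(np.sum(np.conj(r4[c, d, :, :]) * block))
    return phi


def apply_step(sm: SpectralMatrix, phi_i: np.ndarray, phi_o: np.ndarray) -> SpectralMatrix:
    """Multiply exp(i phi_o(k_o)) exp(i phi_i(k_i)) onto the matrix.

    Phase-only: per-entry modulus and Frobenius norm are preserved exactly.
    """
    r4 = sm.as4d()
    out = (
        np.exp(1j * phi_o)[:, :, None, None]
        * np.exp(1j * phi_i)[None, None, :, :]
        * r4
    )
    return SpectralMatrix(
        data=out.reshape(sm.data.shape), optics=sm.optics,
        out_y_px=sm.out_y_px, out_x_px=sm.out_x_px,
        in_y_px=sm.in_y_px, in_x_px=sm.in_x_px, meta=dict(sm.meta),
    )


def confocal_from_spectrum(spectrum: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Complex confocal (diagonal) values on the scan grid from R_CLASS(Δk).

    The space-domain diagonal is the inverse transform of the CLASS spectrum;
    Δk components beyond the scan-lattice zone fold back (alias) onto the
    lattice, exactly as sampling the diagonal does.
    """
    ny, nx = grid_shape
    folded = np.zeros(grid_shape, dtype=complex)
    dy = (np.arange(2 * ny - 1) - (ny - 1) + ny // 2) % ny
    dx = (np.arange(2 * nx - 1) - (nx - 1) + nx // 2) % nx
    np.add.at(folded, (dy[:, None], dx[None, :]), spectrum)
    return cidft2(folded) / math.sqrt(ny * nx)


def _masked_rms(phi: np.ndarray, mask: np.ndarray) -> float:
    """RMS of a phase increment over the mask after piston removal."""
    if not mask.any():
        return 0.0
    vals = phi[mask]
    piston = np.angle(np.mean(np.exp(1j * vals)))
    resid = wrap_phase(vals - piston)
    return float(np.sqrt(np.mean(resid**2)))


@dataclass
class ClassResult:
    """Output of :func:`run_class`.

    ``phi_i`` / ``phi_o`` are the *estimated aberrations* (the negated
    accumulated correction, wrapped, piston removed); ``correction_i`` /
    ``correction_o`` the raw accumulated increments.  ``spectral_corrected``
    is ``R~_c = P~_o* R~ P~_i*``, a phase-only transform of the input;
    ``image`` is the CLASS image |diag R_c|^2 on the scan grid.
    """

    phi_i: PupilPhase
    phi_o: PupilPhase
    correction_i: np.ndarray
    correction_o: np.ndarray
    spectral_corrected: SpectralMatrix
    image: np.ndarray
    log: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    def matrix_corrected(self) -> ReflectionMatrix:
        """Corrected space-domain matrix R_c (computed on demand)."""
        return from_spectral(self.spectral_corrected)


def run_class(
    sm: SpectralMatrix, tol_rms_rad: float = 0.01, max_iter: int = 50
) -> ClassResult:
    """Iterate the CLASS update until the phase increments stall.

    Stops when the piston-removed RMS (over the NA mask) of both increments
    drops below ``tol_rms_rad`` or after ``max_iter`` iterations (flagged,
    not fatal).  Deterministic: no randomness anywhere.
    """
    _require_square(sm)
    ny, nx = sm.in_shape
    mask = sm.mask_in
    acc_i = np.zeros((ny, nx))
    acc_o = np.zeros((ny, nx))
    current = sm
    log: list[dict] = []
    converged = False
    n = 0

    spectrum = class_spectrum(current)
    prev_objective = float(np.sum(np.abs(spectrum) ** 2))
    for n in range(1, max_iter + 1):
        # sequential update: the output estimate is taken from the matrix
        # with the input increment already applied (and the CLASS spectrum
        # recomputed), which removes the overshoot of estimating both sides
        # from the same spectrum and keeps the objective non-decreasing
        phi_i = input_phase_step(current, spectrum)
        current = apply_step(current, phi_i, np.zeros_like(phi_i))
        acc_i += phi_i
        spectrum = class_spectrum(current)
        phi_o = output_phase_step(current, spectrum)
        current = apply_step(current, np.zeros_like(phi_o), phi_o)
        acc_o += phi_o
        spectrum = class_spectrum(current)
        objective = float(np.sum(np.abs(spectrum) ** 2))
        rms_i = _masked_rms(phi_i, mask)
        rms_o = _masked_rms(phi_o, mask)
        log.append({"n": n, "objective": objective, "rms_i": rms_i, "rms_o": rms_o})
        # small increments alone are not convergence: early iterations can
        # take slow-growing steps while coherence bootstraps, so also require
        # the confocal-intensity objective to have stagnated
        stalled = abs(objective - prev_objective) < 1e-6 * max(prev_objective, 1e-300)
        prev_objective = objective
        if rms_i < tol_rms_rad and rms_o < tol_rms_rad and stalled:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"CLASS did not reach tol={tol_rms_rad} rad in {max_iter} iterations",
            RuntimeWarning,
        )

    image = np.abs(confocal_from_spectrum(spectrum, (ny, nx))) ** 2
    dk = sm.dk_in[0]

    def _report(acc: np.ndarray, side: str) -> PupilPhase:
        est = np.where(mask, -acc, 0.0)
        piston = np.angle(np.mean(np.exp(1j * est[mask]))) if mask.any() else 0.0
        est = np.where(mask, wrap_phase(est - piston), 0.0)
        return PupilPhase(phase=est, dk=dk, mask=mask, side=side)

    return ClassResult(
        phi_i=_report(acc_i, "input"),
        phi_o=_report(acc_o, "output"),
        correction_i=acc_i,
        correction_o=acc_o,
        spectral_corrected=current,
        image=image,
        log=log,
        converged=converged,
        n_iter=n,
    )


def class_image(result: ClassResult) -> np.ndarray:
    """Aberration-corrected confocal intensity |diag R_c|^2 on the scan grid."""
    return result.image
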