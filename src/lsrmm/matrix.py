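"""Reflection matrices in position and spatial-frequency space.

The time-gated reflection matrix ``R(r_o; r_i)`` collects one de-scanned
field image per scan position: column ``j`` is the lab-frame field for
illumination at ``r_i = j``, flattened in C order over ``(y, x)`` (x fastest);
the flattening is recorded on the object so diagonal extraction is
unambiguous.  Converting both sides to the spatial-frequency basis,
``R~ = F R F^-1`` with unitary centered DFTs, turns shift-invariant
illumination/detection blurs into diagonal pupil factors:
``R~(k_o; k_i) = exp(i phi_o(k_o)) O~(k_o - k_i) exp(i phi_i(k_i))`` within an
isoplanatic patch, which is the structure the CLASS solver exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fft import cdft2, cidft2, k_axis, na_mask
from .forward import FieldStack, InvalidConfiguration, OpticsConfig


@dataclass
class ReflectionMatrix:
    """Space-domain matrix R(r_o; r_i).

    ``data`` has shape (N_o, N_i).  Rows are lab-frame output pixels on a
    regular lattice given by the absolute pixel axes ``out_y_px`` /
    ``out_x_px`` (C-order flattening, x fastest); columns likewise via
    ``in_y_px`` / ``in_x_px``.  Output and input lattices may differ (e.g.
    fine camera pitch vs the scan lattice).
    """

    data: np.ndarray
    optics: OpticsConfig
    out_y_px: np.ndarray
    out_x_px: np.ndarray
    in_y_px: np.ndarray
    in_x_px: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        for name in ("out_y_px", "out_x_px", "in_y_px", "in_x_px"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        n_o = self.out_y_px.size * self.out_x_px.size
        n_i = self.in_y_px.size * self.in_x_px.size
        if self.data.shape != (n_o, n_i):
            raise InvalidConfiguration(
                f"matrix shape {self.data.shape} does not match index maps "
                f"({n_o}, {n_i})"
            )

    @property
    def out_shape(self) -> tuple[int, int]:
        return self.out_y_px.size, self.out_x_px.size

    @property
    def in_shape(self) -> tuple[int, int]:
        return self.in_y_px.size, self.in_x_px.size

    def as4d(self) -> np.ndarray:
        """View as (out_y, out_x, in_y, in_x)."""
        return self.data.reshape(self.out_shape + self.in_shape)

    def is_square_lattice(self) -> bool:
        return (
            np.array_equal(self.out_y_px, self.in_y_px)
            and np.array_equal(self.out_x_px, self.in_x_px)
        )

    def diagonal(self) -> np.ndarray:
        """Confocal entries R(r; r) on the input lattice (2-D array).

        Defined only where every input position appears in the output
        lattice.
        """
        r4 = self.as4d()
        iy = _index_in(self.in_y_px, self.out_y_px)
        ix = _index_in(self.in_x_px, self.out_x_px)
        out = np.empty(self.in_shape, dtype=self.data.dtype)
        for a in range(self.in_shape[0]):
            for b in range(self.in_shape[1]):
                out[a, b] = r4[iy[a], ix[b], a, b]
        return out


def _index_in(needles: np.ndarray, haystack: np.ndarray) -> np.ndarray:
    """Indices of each needle in haystack; error if any is missing."""
    lookup = {int(v): i for i, v in enumerate(haystack)}
    try:
        return np.array([lookup[int(v)] for v in needles], dtype=int)
    except KeyError as exc:  # pragma: no cover - message path
        raise InvalidConfiguration(
            f"position {exc} not present in the output lattice; "
            "diagonal is undefined"
        ) from None


@dataclass
class SpectralMatrix:
    """k-space matrix R~(k_o; k_i) with its grid spacings and NA masks.

    ``data`` has shape (N_o, N_i) over centered k-grids; ``dk_out`` /
    ``dk_in`` are (dky, dkx) in rad/µm.  Entries outside the NA disk are
    retained; ``mask_out`` / ``mask_in`` flag the disk.  The spatial lattices
    that produced the matrix are kept so the transform is invertible.
    """

    data: np.ndarray
    optics: OpticsConfig
    out_y_px: np.ndarray
    out_x_px: np.ndarray
    in_y_px: np.ndarray
    in_x_px: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def out_shape(self) -> tuple[int, int]:
        return self.out_y_px.size, self.out_x_px.size

    @property
    def in_shape(self) -> tuple[int, int]:
        return self.in_y_px.size, self.in_x_px.size

    def as4d(self) -> np.ndarray:
        return self.data.reshape(self.out_shape + self.in_shape)

    def _pitch(self, axis_px: np.ndarray) -> float:
        steps = np.diff(axis_px)
        if axis_px.size > 1 and not np.all(steps == steps[0]):
            raise InvalidConfiguration("spatial lattice is not regular")
        step = int(steps[0]) if axis_px.size > 1 else 1
        return step * self.optics.pixel_pitch

    @property
    def dk_out(self) -> tuple[float, float]:
        ny, nx = self.out_shape
        return (
            2 * np.pi / (ny * self._pitch(self.out_y_px)),
            2 * np.pi / (nx * self._pitch(self.out_x_px)),
        )

    @property
    def dk_in(self) -> tuple[float, float]:
        ny, nx = self.in_shape
        return (
            2 * np.pi / (ny * self._pitch(self.in_y_px)),
            2 * np.pi / (nx * self._pitch(self.in_x_px)),
        )

    @property
    def mask_out(self) -> np.ndarray:
        return na_mask(self.out_shape, self._pitch(self.out_y_px), self.optics.k_na)

    @property
    def mask_in(self) -> np.ndarray:
        return na_mask(self.in_shape, self._pitch(self.in_y_px), self.optics.k_na)

    def k_axes_out(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.out_shape
        return (
            k_axis(ny, self._pitch(self.out_y_px)),
            k_axis(nx, self._pitch(self.out_x_px)),
        )


# ---------------------------------------------------------------------------
# de-scan / lab conversions
# ---------------------------------------------------------------------------


def descan_to_lab(stack: FieldStack) -> FieldStack:
    """Shift each de-scanned frame by +r_i into the absolute (lab) frame.

    The output window is the full periodic grid; pixels outside the measured
    detection window of a frame are zero-filled (honest zeros: no data).
    """
    if stack.frame != "descanned":
        raise InvalidConfiguration("descan_to_lab expects a de-scanned stack")
    n = stack.optics.grid_size
    c = n // 2
    fy, fx = stack.frame_shape
    out = np.zeros(stack.data.shape[:2] + (n, n), dtype=stack.data.dtype)
    y0, x0 = c - fy // 2, c - fx // 2
    for a, sy in enumerate(stack.scan_y_px):
        for b, sx in enumerate(stack.scan_x_px):
            frame_full = np.zeros((n, n), dtype=stack.data.dtype)
            frame_full[y0 : y0 + fy, x0 : x0 + fx] = stack.data[a, b]
            out[a, b] = np.roll(frame_full, (sy - c, sx - c), axis=(0, 1))
    return FieldStack(
        data=out, optics=stack.optics, scan_y_px=stack.scan_y_px,
        scan_x_px=stack.scan_x_px, frame="lab", truth=dict(stack.truth),
    )


def lab_to_descan(stack: FieldStack, fod_px: int | None = None) -> FieldStack:
    """Inverse of :func:`descan_to_lab` (crop back to a detection window)."""
    if stack.frame != "lab":
        raise InvalidConfiguration("lab_to_descan expects a lab-frame stack")
    n = stack.optics.grid_size
    c = n // 2
    if fod_px is None:
        fod_px = n
    half = fod_px // 2
    out = np.zeros(stack.data.shape[:2] + (fod_px, fod_px), dtype=stack.data.dtype)
    for a, sy in enumerate(stack.scan_y_px):
        for b, sx in enumerate(stack.scan_x_px):
            cam = np.roll(stack.data[a, b], (c - sy, c - sx), axis=(0, 1))
            out[a, b] = cam[c - half : c - half + fod_px, c - half : c - half + fod_px]
    return FieldStack(
        data=out, optics=stack.optics, scan_y_px=stack.scan_y_px,
        scan_x_px=stack.scan_x_px, frame="descanned", truth=dict(stack.truth),
    )


# ---------------------------------------------------------------------------
# assembly and basis changes
# ---------------------------------------------------------------------------


def assemble_matrix(stack: FieldStack) -> ReflectionMatrix:
    """Column-stack lab-frame images into R(r_o; r_i).

    Rows run over every pixel of the lab-frame window at camera pitch;
    columns over scan positions.
    """
    if stack.frame != "lab":
        raise InvalidConfiguration("assemble_matrix expects a lab-frame stack")
    n = stack.optics.grid_size
    n_s = stack.n_scan
    data = stack.data.reshape(n_s, n * n).T.copy()
    return ReflectionMatrix(
        data=data, optics=stack.optics,
        out_y_px=np.arange(n), out_x_px=np.arange(n),
        in_y_px=stack.scan_y_px, in_x_px=stack.scan_x_px,
        meta={"flatten": "C order over (y, x), x fastest"},
    )


def crop_to_scan_grid(rm: ReflectionMatrix) -> ReflectionMatrix:
    """Resample the output window onto the input (scan) lattice -> square R."""
    r4 = rm.as4d()
    iy = _index_in(rm.in_y_px, rm.out_y_px)
    ix = _index_in(rm.in_x_px, rm.out_x_px)
    sub = r4[np.ix_(iy, ix)].reshape(
        rm.in_y_px.size * rm.in_x_px.size, rm.data.shape[1]
    )
    return ReflectionMatrix(
        data=sub, optics=rm.optics,
        out_y_px=rm.in_y_px, out_x_px=rm.in_x_px,
        in_y_px=rm.in_y_px, in_x_px=rm.in_x_px, meta=dict(rm.meta),
    )


def to_spectral(rm: ReflectionMatrix) -> SpectralMatrix:
    """Unitary change of basis R~ = F R F^-1.

    The centered forward DFT acts on the output side (each column, viewed as
    an image over the output lattice) and the centered inverse DFT on the
    input side.  Requires matching output/input lattices (use
    :func:`crop_to_scan_grid` or the local module's padding first); energy is
    preserved to rounding.
    """
    if not rm.is_square_lattice():
        raise InvalidConfiguration(
            "to_spectral needs matching output/input lattices; "
            "use crop_to_scan_grid or local.pad_to_square first"
        )
    r4 = rm.as4d()
    sk = cdft2(r4, axes=(0, 1))
    sk = cidft2(sk, axes=(2, 3))
    return SpectralMatrix(
        data=sk.reshape(rm.data.shape), optics=rm.optics,
        out_y_px=rm.out_y_px, out_x_px=rm.out_x_px,
        in_y_px=rm.in_y_px, in_x_px=rm.in_x_px, meta=dict(rm.meta),
    )


def from_spectral(sm: SpectralMatrix) -> ReflectionMatrix:
    """Inverse of :func:`to_spectral`."""
    s4 = sm.as4d()
    r4 = cidft2(s4, axes=(0, 1))
    r4 = cdft2(r4, axes=(2, 3))
    return ReflectionMatrix(
        data=r4.reshape(sm.data.shape), optics=sm.optics,
        out_y_px=sm.out_y_px, out_x_px=sm.out_x_px,
        in_y_px=sm.in_y_px, in_x_px=sm.in_x_px, meta=dict(sm.meta),
    )


def ocm_image(rm: ReflectionMatrix, pinhole_radius_airy: float = 1.0) -> np.ndarray:
    """Confocal (OCM) intensity image from the matrix diagonal.

    Per scan position the intensity |E_lab(r_o; r_i)|^2 is summed over output
    pixels within ``pinhole_radius_airy`` Airy radii (1 Airy radius =
    0.61 lambda / NA) of r_i; radius 0 gives the squared modulus of the exact
    diagonal.
    """
    if pinhole_radius_airy < 0:
        raise InvalidConfiguration("pinhole radius must be >= 0")
    if pinhole_radius_airy == 0:
        return np.abs(rm.diagonal()) ** 2

    opt = rm.optics
    radius_um = pinhole_radius_airy * 0.61 * opt.wavelength / opt.numerical_aperture
    r4 = rm.as4d()
    yy = rm.out_y_px[:, None] * opt.pixel_pitch
    xx = rm.out_x_px[None, :] * opt.pixel_pitch
    img = np.empty(rm.in_shape, dtype=float)
    for a, sy in enumerate(rm.in_y_px):
        for b, sx in enumerate(rm.in_x_px):
            d2 = (yy - sy * opt.pixel_pitch) ** 2 + (xx - sx * opt.pixel_pitch) ** 2
            sel = d2 <= radius_um**2
            img[a, b] = float(np.sum(np.abs(r4[:, :, a, b][sel]) ** 2))
    return img
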