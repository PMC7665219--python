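"""Forward model: scanned reflection-matrix data through an aberrating layer.

This module simulates the raw data of laser-scanning reflection-matrix
microscopy (LS-RMM): a diffraction-limited focus is raster-scanned across the
sample, and for every illumination position ``r_i`` a time-gated complex field
``E_cam(r_cam; r_i)`` is recorded in the de-scanned camera frame.  The scalar
model for a single sample plane behind one effective aberrating layer is

    E_cam(r_cam; r_i) = sum_r P_o(r_cam - r) O(r) P_i(r - r_i) + E_M,

where ``O`` is the complex amplitude reflectance of the object, ``P_i`` /
``P_o`` are the illumination / detection amplitude point-spread functions
generated by the pupil phase maps ``phi_i(k)`` / ``phi_o(k)``, and ``E_M`` is
time-gated multiple-scattering speckle, modelled as white circular complex
Gaussian noise calibrated to a target single-to-multiple-scattering confocal
intensity ratio (ssmr).

The simulation lives on a periodic pixel grid (circular convolutions); the
scan lattice steps an integer number of pixels so that de-scanning is an exact
shift and never interpolates.

Analytic planners reproduce the acquisition bookkeeping of the instrument:
with diffraction limit ``delta_d = lambda / (2 alpha)``, a camera frame rate
``f_cam = r / sqrt(FOD)``, ``N_s = FOI / delta_d^2`` scan positions, total
time ``T = N_s / f_cam``, and ``N_c = pi (sqrt(FOD) / (2 delta_d))^2``
correctable pupil modes set by the field of detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._fft import cidft2, k_axis, na_mask, wrap_phase


class InvalidConfiguration(ValueError):
    """Raised when optics / acquisition parameters are inconsistent."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticsConfig:
    """Optical and sampling parameters of the simulated microscope.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in µm.
    numerical_aperture : float
        Objective NA (0 < NA <= 1.33).
    pixel_pitch : float
        Sample-plane pixel pitch of the simulation grid in µm.  Must divide
        the scan step (= ``delta_d`` rounded to pixels) an integer number of
        times so de-scan shifts are exact.
    grid_size : int
        Pixels per side of the (square, periodic) simulation field.
    """

    wavelength: float
    numerical_aperture: float
    pixel_pitch: float
    grid_size: int

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise InvalidConfiguration("wavelength must be positive")
        if not (0 < self.numerical_aperture <= 1.33):
            raise InvalidConfiguration("numerical_aperture must be in (0, 1.33]")
        if not (self.pixel_pitch > 0):
            raise InvalidConfiguration("pixel_pitch must be positive")
        if self.grid_size < 4 or self.grid_size % 2:
            raise InvalidConfiguration("grid_size must be an even integer >= 4")
        ratio = self.delta_d / self.pixel_pitch
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise InvalidConfiguration(
                "pixel_pitch must divide the scan step delta_d exactly "
                f"(delta_d/pitch = {ratio:g})"
            )

    @property
    def delta_d(self) -> float:
        """Diffraction-limited resolution lambda / (2 NA), µm (recomputed)."""
        return self.wavelength / (2.0 * self.numerical_aperture)

    @property
    def k_na(self) -> float:
        """Pupil cutoff 2 pi NA / lambda in rad/µm."""
        return 2.0 * np.pi * self.numerical_aperture / self.wavelength

    @property
    def scan_step_px(self) -> int:
        """Scan interval delta_d expressed in integer pixels."""
        return int(round(self.delta_d / self.pixel_pitch))

    @property
    def extent(self) -> float:
        """Physical side length of the simulation field, µm."""
        return self.grid_size * self.pixel_pitch

    @classmethod
    def nyquist(
        cls, wavelength: float, numerical_aperture: float, grid_size: int
    ) -> "OpticsConfig":
        """Default sampling: pitch = delta_d / 2, scan step = 2 pixels."""
        delta_d = wavelength / (2.0 * numerical_aperture)
        return cls(wavelength, numerical_aperture, delta_d / 2.0, grid_size)


@dataclass(frozen=True)
class AcquisitionPlan:
    """Analytic acquisition bookkeeping for a full reflection matrix."""

    foi_side: float  # µm
    fod_side: float  # µm
    camera_rate_coefficient: float  # 1/µm
    n_scan: int  # number of scan positions N_s
    f_cam: float  # camera frame rate, Hz
    total_time: float  # T = N_s / f_cam, s
    n_modes: int  # correctable pupil modes N_c


def plan_acquisition(
    optics: OpticsConfig, foi_side: float, fod_side: float, r: float
) -> AcquisitionPlan:
    """Closed-form acquisition planner.

    ``N_c = round(pi (FOD_side / (2 delta_d))^2)`` counts the free angular
    modes of a circular pupil resolvable with a detection window of side
    ``FOD_side``; ``N_s = round(FOI_side^2 / delta_d^2)`` counts scan
    positions at the diffraction-limited interval; ``f_cam = r / FOD_side``
    and ``T = N_s / f_cam``.
    """
    if foi_side <= 0 or fod_side <= 0 or r <= 0:
        raise InvalidConfiguration("FOI, FOD and r must all be positive")
    dd = optics.delta_d
    n_modes = int(round(math.pi * (fod_side / (2.0 * dd)) ** 2))
    n_scan = int(round(foi_side**2 / dd**2))
    f_cam = r / fod_side
    return AcquisitionPlan(
        foi_side=foi_side,
        fod_side=fod_side,
        camera_rate_coefficient=r,
        n_scan=n_scan,
        f_cam=f_cam,
        total_time=n_scan / f_cam,
        n_modes=n_modes,
    )


# ---------------------------------------------------------------------------
# pupils and PSFs
# ---------------------------------------------------------------------------


@dataclass
class PupilPhase:
    """Pupil phase map phi(k) on a centered transverse-wavevector grid.

    ``phase`` is in radians, finite inside the boolean NA ``mask`` and held at
    zero outside; ``dk`` is the grid spacing in rad/µm; ``side`` labels the
    pupil as ``"input"`` (illumination) or ``"output"`` (detection).
    """

    phase: np.ndarray
    dk: float
    mask: np.ndarray
    side: str = "input"

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.phase.shape != self.mask.shape:
            raise InvalidConfiguration("phase and mask shapes differ")
        if not np.all(np.isfinite(self.phase[self.mask])):
            raise InvalidConfiguration("phase must be finite inside the NA mask")
        self.phase = np.where(self.mask, self.phase, 0.0)

    @property
    def wrapped(self) -> np.ndarray:
        """Phase wrapped to (-pi, pi], zero outside the mask."""
        return np.where(self.mask, wrap_phase(self.phase), 0.0)

    def pupil_function(self) -> np.ndarray:
        """Complex pupil mask * exp(i phi)."""
        return np.where(self.mask, np.exp(1j * self.phase), 0.0)


def _noll_to_nm(j: int) -> tuple[int, int]:
    """Noll single index -> (radial order n, azimuthal frequency m)."""
    if j < 1:
        raise InvalidConfiguration("Noll index starts at 1")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, abs(m) * (1 if m >= 0 else -1)


def _zernike(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Noll-normalised Zernike polynomial Z_n^m on the unit disk."""
    am = abs(m)
    radial = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)
            )
        )
        radial += c * rho ** (n - 2 * k)
    norm = math.sqrt(2 * (n + 1)) if m != 0 else math.sqrt(n + 1)
    if m > 0:
        return norm * radial * np.cos(am * theta)
    if m < 0:
        return norm * radial * np.sin(am * theta)
    return norm * radial


def speckle_length_for_modes(optics: OpticsConfig, n_modes: float) -> float:
    """Correlation length (rad/µm) giving ~``n_modes`` independent pupil cells.

    Modes are counted as NA-disk area divided by the correlation area of the
    underlying complex Gaussian field: ``n = pi k_NA^2 / ell^2``.
    """
    if n_modes <= 0:
        raise InvalidConfiguration("n_modes must be positive")
    return optics.k_na * math.sqrt(math.pi / n_modes)


def make_pupil_phase(
    optics: OpticsConfig,
    model: str,
    params: dict | None = None,
    seed: int | None = None,
    side: str = "input",
) -> PupilPhase:
    """Generate a pupil phase screen on the full simulation k-grid.

    ``model="zernike"`` takes ``params={"coeffs": {noll_index: rad}}`` and is
    deterministic.  ``model="bandlimited_speckle"`` takes either
    ``params={"corr_length": rad_per_um}`` or ``{"n_modes": count}`` and draws
    the phase as the argument of a Gaussian random field smoothed to the
    requested correlation length — a stand-in for the speckle-like pupil maps
    produced by bone, not a physical model of any particular medium.  The
    screen is zero-mean (circular mean removed) inside the NA mask.
    """
    params = dict(params or {})
    n = optics.grid_size
    dk = 2.0 * np.pi / optics.extent
    mask = na_mask((n, n), optics.pixel_pitch, optics.k_na)
    ky = k_axis(n, optics.pixel_pitch)
    kyg, kxg = np.meshgrid(ky, ky, indexing="ij")

    if model == "zernike":
        coeffs = params.get("coeffs", {})
        rho = np.sqrt(kyg**2 + kxg**2) / optics.k_na
        theta = np.arctan2(kyg, kxg)
        phase = np.zeros((n, n))
        for j, c in coeffs.items():
            nn, mm = _noll_to_nm(int(j))
            phase += float(c) * _zernike(nn, mm, rho, theta)
    elif model == "bandlimited_speckle":
        if "corr_length" in params:
            ell = float(params["corr_length"])
        elif "n_modes" in params:
            ell = speckle_length_for_modes(optics, float(params["n_modes"]))
        else:
            raise InvalidConfiguration(
                "bandlimited_speckle needs corr_length or n_modes"
            )
        if ell <= dk:
            raise InvalidConfiguration(
                f"correlation length {ell:g} must exceed the k-grid spacing {dk:g}"
            )
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        g = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        # Gaussian filter sigma such that the field correlation area is ell^2
        sigma_px = ell / dk / math.sqrt(2.0 * math.pi)
        g = gaussian_filter(g.real, sigma_px) + 1j * gaussian_filter(g.imag, sigma_px)
        phase = np.angle(g)
    else:
        raise InvalidConfiguration(f"unknown pupil model {model!r}")

    # remove piston (circular mean) inside the mask
    piston = np.angle(np.mean(np.exp(1j * phase[mask]))) if mask.any() else 0.0
    phase = wrap_phase(phase - piston)
    phase = np.where(mask, phase, 0.0)
    return PupilPhase(phase=phase, dk=dk, mask=mask, side=side)


def flat_pupil(optics: OpticsConfig, side: str = "input") -> PupilPhase:
    """Aberration-free pupil (phi = 0 on the NA disk)."""
    return make_pupil_phase(optics, "zernike", {"coeffs": {}}, side=side)


def psf_from_pupil(pupil: PupilPhase) -> np.ndarray:
    """Amplitude PSF: centered inverse DFT of the complex pupil function.

    Normalised so the flat-phase PSF of the same mask has unit peak amplitude
    at the central (zero-shift) pixel.
    """
    p = pupil.pupil_function()
    n_open = int(pupil.mask.sum())
    if n_open == 0:
        raise InvalidConfiguration("empty NA mask")
    psf = cidft2(p)
    # flat-pupil peak of the ortho IDFT is sum(mask) / sqrt(N_total)
    flat_peak = n_open / math.sqrt(p.size)
    return psf / flat_peak


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


@dataclass
class ObjectMap:
    """Complex amplitude reflectance O(r) on the sample-plane grid."""

    reflectance: np.ndarray
    optics: OpticsConfig

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance)
        n = self.optics.grid_size
        if self.reflectance.shape != (n, n):
            raise InvalidConfiguration("object grid must match optics.grid_size")
        if np.max(np.abs(self.reflectance)) > 1 + 1e-12:
            raise InvalidConfiguration("|O(r)| must be <= 1 everywhere")

    @property
    def extent(self) -> float:
        return self.optics.extent


def make_siemens_star(
    n_spokes: int, side_px: int, optics: OpticsConfig | None = None
) -> ObjectMap | np.ndarray:
    """Binary-amplitude Siemens star with ``n_spokes`` alternating sectors."""
    if n_spokes % 2 or n_spokes < 2:
        raise InvalidConfiguration("n_spokes must be even and >= 2")
    c = side_px // 2
    y, x = np.mgrid[0:side_px, 0:side_px]
    theta = np.arctan2(y - c + 0.0, x - c + 0.0)
    sector = np.floor((theta + np.pi) / (2.0 * np.pi / n_spokes)).astype(int)
    star = (sector % 2).astype(float)
    star[c, c] = 1.0
    if optics is None:
        return star
    return ObjectMap(reflectance=star, optics=optics)


def make_filaments(
    n: int,
    width_px: float,
    seed: int,
    side_px: int = 64,
    optics: OpticsConfig | None = None,
) -> ObjectMap | np.ndarray:
    """Smooth random curvilinear phantoms (myelin-like fibres), amplitude <= 1."""
    if n < 1 or width_px <= 0:
        raise InvalidConfiguration("need n >= 1 filaments of positive width")
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    img = np.zeros((side_px, side_px))
    t = np.linspace(0.0, 1.0, 8 * side_px)
    for _ in range(n):
        # random smooth curve: low-order Fourier series in each coordinate
        coef = rng.standard_normal((2, 4)) * side_px / 6.0
        start = rng.uniform(0.15, 0.85, size=2) * side_px
        yy = start[0] + sum(
            coef[0, m] * np.sin((m + 1) * np.pi * t + rng.uniform(0, 2 * np.pi))
            for m in range(4)
        )
        xx = start[1] + sum(
            coef[1, m] * np.sin((m + 1) * np.pi * t + rng.uniform(0, 2 * np.pi))
            for m in range(4)
        )
        iy = np.clip(np.round(yy).astype(int), 0, side_px - 1)
        ix = np.clip(np.round(xx).astype(int), 0, side_px - 1)
        img[iy, ix] = 1.0
    img = gaussian_filter(img, width_px / 2.355)  # FWHM -> sigma
    if img.max() > 0:
        img = img / img.max()
    if optics is None:
        return img
    return ObjectMap(reflectance=img, optics=optics)


def make_points(
    n: int, side_px: int, seed: int, min_sep_px: int = 8,
    optics: OpticsConfig | None = None,
) -> ObjectMap | np.ndarray:
    """Sparse unit-amplitude point scatterers (synthetic bead phantom)."""
    rng = np.random.default_rng(seed)
    img = np.zeros((side_px, side_px))
    pts: list[tuple[int, int]] = []
    tries = 0
    while len(pts) < n and tries < 10000:
        tries += 1
        y, x = rng.integers(side_px // 8, side_px - side_px // 8, size=2)
        if all(max(abs(y - a), abs(x - b)) >= min_sep_px for a, b in pts):
            pts.append((int(y), int(x)))
    for y, x in pts:
        img[y, x] = 1.0
    if optics is None:
        return img
    return ObjectMap(reflectance=img, optics=optics)


# ---------------------------------------------------------------------------
# scanning simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Multiple-scattering speckle model: white circular complex Gaussian.

    ``ssmr`` is the target ratio of the mean confocal signal intensity to the
    mean multiple-scattering intensity per pixel; identical seeds give
    bit-identical realisations.
    """

    ssmr: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.ssmr > 0):
            raise InvalidConfiguration("ssmr must be positive")


@dataclass
class FieldStack:
    """De-scanned (or lab-frame) complex field frames, one per scan position.

    ``data`` has shape (scan_y, scan_x, frame_y, frame_x).  ``scan_y_px`` /
    ``scan_x_px`` hold the absolute grid-pixel coordinates of the scan
    lattice.  ``frame`` is ``"descanned"`` (camera coordinates ``r_cam``,
    focus at the frame centre) or ``"lab"`` (absolute coordinates ``r_o``).
    ``truth`` optionally carries the ground-truth object, pupil screens and
    noise power of a synthetic stack.
    """

    data: np.ndarray
    optics: OpticsConfig
    scan_y_px: np.ndarray
    scan_x_px: np.ndarray
    frame: str = "descanned"
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.scan_y_px = np.asarray(self.scan_y_px, dtype=int)
        self.scan_x_px = np.asarray(self.scan_x_px, dtype=int)
        if self.data.ndim != 4:
            raise InvalidConfiguration("stack must be 4-D (sy, sx, fy, fx)")
        if self.data.shape[:2] != (self.scan_y_px.size, self.scan_x_px.size):
            raise InvalidConfiguration("scan grid does not match stack shape")
        if self.frame not in ("descanned", "lab"):
            raise InvalidConfiguration("frame must be 'descanned' or 'lab'")

    @property
    def n_scan(self) -> int:
        return self.scan_y_px.size * self.scan_x_px.size

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]


def default_scan_grid(optics: OpticsConfig) -> tuple[np.ndarray, np.ndarray]:
    """Scan lattice at the diffraction-limited interval covering the field."""
    step = optics.scan_step_px
    pos = np.arange(0, optics.grid_size, step)
    return pos, pos


def _signal_frames(
    obj: ObjectMap,
    screens: Sequence[tuple[np.ndarray, PupilPhase, PupilPhase]],
    scan_y: np.ndarray,
    scan_x: np.ndarray,
    fod_px: int,
) -> np.ndarray:
    """Noise-free de-scanned frames via circular FFT convolution."""
    n = obj.optics.grid_size
    c = n // 2
    half = fod_px // 2
    out = np.zeros((scan_y.size, scan_x.size, fod_px, fod_px), dtype=complex)
    o_arr = np.asarray(obj.reflectance, dtype=complex)
    for patch_mask, phi_i, phi_o in screens:
        h_i = psf_from_pupil(phi_i)
        h_o = psf_from_pupil(phi_o)
        H_o = np.fft.fft2(np.fft.ifftshift(h_o))
        for a, sy in enumerate(scan_y):
            for b, sx in enumerate(scan_x):
                if not patch_mask[a, b]:
                    continue
                illum = np.roll(h_i, (sy - c, sx - c), axis=(0, 1))
                e_lab = np.fft.ifft2(np.fft.fft2(o_arr * illum) * H_o)
                e_cam = np.roll(e_lab, (c - sy, c - sx), axis=(0, 1))
                out[a, b] = e_cam[c - half : c - half + fod_px,
                                  c - half : c - half + fod_px]
    return out


def simulate_scan(
    obj: ObjectMap,
    phi_i: PupilPhase,
    phi_o: PupilPhase,
    noise: NoiseModel | None = None,
    scan_y_px: np.ndarray | None = None,
    scan_x_px: np.ndarray | None = None,
    fod_px: int | None = None,
) -> FieldStack:
    """Simulate a de-scanned field stack for one isoplanatic patch.

    The pupils are shift-invariant over the field; spatially varying
    aberrations are simulated with :func:`simulate_scan_patches`.  The scan
    lattice defaults to the diffraction-limited interval covering the whole
    (periodic) grid and the detection window defaults to the full grid.
    """
    optics = obj.optics
    n = optics.grid_size
    if scan_y_px is None or scan_x_px is None:
        scan_y_px, scan_x_px = default_scan_grid(optics)
    scan_y_px = np.asarray(scan_y_px, dtype=int)
    scan_x_px = np.asarray(scan_x_px, dtype=int)
    full = np.ones((scan_y_px.size, scan_x_px.size), dtype=bool)
    return simulate_scan_patches(
        obj, [(full, phi_i, phi_o)], noise=noise,
        scan_y_px=scan_y_px, scan_x_px=scan_x_px, fod_px=fod_px,
    )


def simulate_scan_patches(
    obj: ObjectMap,
    patches: Sequence[tuple[np.ndarray, PupilPhase, PupilPhase]],
    noise: NoiseModel | None = None,
    scan_y_px: np.ndarray | None = None,
    scan_x_px: np.ndarray | None = None,
    fod_px: int | None = None,
) -> FieldStack:
    """Simulate with piecewise-constant screens (anisoplanatic composition).

    ``patches`` is a list of ``(scan_mask, phi_i, phi_o)``; every scan
    position uses the screens of the patch it belongs to.  The masks must
    partition the scan grid.
    """
    optics = obj.optics
    n = optics.grid_size
    if scan_y_px is None or scan_x_px is None:
        scan_y_px, scan_x_px = default_scan_grid(optics)
    scan_y_px = np.asarray(scan_y_px, dtype=int)
    scan_x_px = np.asarray(scan_x_px, dtype=int)
    if scan_y_px.min() < 0 or scan_y_px.max() >= n or scan_x_px.min() < 0 \
            or scan_x_px.max() >= n:
        raise InvalidConfiguration("scan grid extends beyond the object support")
    if fod_px is None:
        fod_px = n
    if fod_px > n or fod_px % 2:
        raise InvalidConfiguration("fod_px must be even and <= grid_size")

    cover = np.zeros((scan_y_px.size, scan_x_px.size), dtype=int)
    for m, _, _ in patches:
        cover += np.asarray(m, dtype=int)
    if not np.all(cover == 1):
        raise InvalidConfiguration("patch masks must partition the scan grid")

    data = _signal_frames(obj, patches, scan_y_px, scan_x_px, fod_px)
    truth: dict = {
        "object": np.asarray(obj.reflectance),
        "patches": [
            {"scan_mask": np.asarray(m, bool), "phi_i": pi, "phi_o": po}
            for m, pi, po in patches
        ],
        "noise_sigma2": 0.0,
    }
    if len(patches) == 1:
        truth["phi_i"] = patches[0][1]
        truth["phi_o"] = patches[0][2]

    if noise is not None:
        c_idx = fod_px // 2
        mean_conf = float(np.mean(np.abs(data[:, :, c_idx, c_idx]) ** 2))
        sigma2 = mean_conf / noise.ssmr
        rng = np.random.default_rng(noise.seed)
        e_m = rng.normal(scale=math.sqrt(sigma2 / 2.0), size=data.shape + (2,))
        data = data + e_m[..., 0] + 1j * e_m[..., 1]
        truth["noise_sigma2"] = sigma2
        truth["ssmr_requested"] = noise.ssmr

    return FieldStack(
        data=data, optics=optics, scan_y_px=scan_y_px, scan_x_px=scan_x_px,
        frame="descanned", truth=truth,
    )
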