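"""Quantitative evaluation: PSF statistics, Strehl ratios, phase-map
agreement and single-to-multiple-scattering ratios.

Strehl ratios are computed against the simulated flat-pupil PSF on the same
grid (not an analytic Airy pattern) so that discretisation cancels; the
on-axis pupil-average form ``S = |<exp(i phi)>_mask|^2`` is also provided
and is exact for zero-tilt screens.  Aberration maps are compared modulo
piston and linear tilt — the degeneracies of the reflection-matrix
factorisation — with circular-aware statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from ._fft import cidft2, wrap_phase
from .forward import (
    FieldStack,
    InvalidConfiguration,
    OpticsConfig,
    PupilPhase,
    simulate_scan_patches,
)
from .matrix import ReflectionMatrix


# ---------------------------------------------------------------------------
# Strehl and PSF statistics
# ---------------------------------------------------------------------------


def strehl_onaxis(phase: np.ndarray, mask: np.ndarray) -> float:
    """On-axis Strehl |<exp(i phi)>|^2 over the pupil mask."""
    if not mask.any():
        raise InvalidConfiguration("empty mask")
    return float(np.abs(np.mean(np.exp(1j * phase[mask]))) ** 2)


def strehl_peak(phase: np.ndarray, mask: np.ndarray) -> float:
    """Peak Strehl: aberrated vs flat PSF peak intensity (tilt-invariant)."""
    p = np.where(mask, np.exp(1j * phase), 0.0)
    psf = np.abs(cidft2(p))
    flat = mask.sum() / math.sqrt(mask.size)
    return float((psf.max() / flat) ** 2)


@dataclass
class PsfReport:
    peak_intensity: float
    strehl: float
    fwhm: float  # µm, along the horizontal line through the peak
    encircled_energy_radius: float  # µm, radius containing 50% of the energy
    multi_lobe: bool  # secondary lobe above half the peak found


def _line_fwhm(profile: np.ndarray, pitch: float) -> float:
    """FWHM of the dominant lobe via linear interpolation of half crossings."""
    i0 = int(np.argmax(profile))
    half = profile[i0] / 2.0
    left = i0
    while left > 0 and profile[left] > half:
        left -= 1
    right = i0
    while right < profile.size - 1 and profile[right] > half:
        right += 1
    # interpolate crossing positions
    if profile[left] <= half < profile[left + 1]:
        fl = left + (half - profile[left]) / (profile[left + 1] - profile[left])
    else:
        fl = float(left)
    if profile[right] <= half < profile[right - 1]:
        fr = right - (half - profile[right]) / (profile[right - 1] - profile[right])
    else:
        fr = float(right)
    return (fr - fl) * pitch


def psf_report(field: np.ndarray, optics: OpticsConfig) -> PsfReport:
    """Characterise a complex (or intensity) PSF field.

    The field is assumed normalised like :func:`lsrmm.forward.psf_from_pupil`
    (flat-pupil peak amplitude = 1), so the Strehl ratio is simply the peak
    intensity.
    """
    inten = np.abs(np.asarray(field)) ** 2
    peak = float(inten.max())
    iy, ix = np.unravel_index(int(np.argmax(inten)), inten.shape)
    fwhm = _line_fwhm(inten[iy, :], optics.pixel_pitch)

    # encircled energy radius (50%) about the peak
    yy, xx = np.mgrid[0 : inten.shape[0], 0 : inten.shape[1]]
    r = np.hypot(yy - iy, xx - ix).ravel() * optics.pixel_pitch
    order = np.argsort(r)
    cum = np.cumsum(inten.ravel()[order])
    half_idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    ee_radius = float(r[order][min(half_idx, r.size - 1)])

    # multi-lobe flag: another pixel above half peak further than one
    # diffraction limit from the main peak
    far = r.reshape(inten.shape) > optics.delta_d
    multi = bool(np.any(inten[far] > 0.5 * peak))

    return PsfReport(
        peak_intensity=peak,
        strehl=peak,
        fwhm=fwhm,
        encircled_energy_radius=ee_radius,
        multi_lobe=multi,
    )


# ---------------------------------------------------------------------------
# phase-map agreement
# ---------------------------------------------------------------------------


def remove_piston_tilt(
    phi: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Best-fit piston + linear tilt removal from a wrapped phase map.

    The tilt is found from the (sub-pixel) peak of the focus formed by
    ``mask exp(i phi)`` — a linear pupil phase is exactly a focal shift —
    then the circular-mean piston of the residual is removed.  Returns the
    wrapped residual (zero outside the mask) and (tilt_y, tilt_x, piston) in
    radians per k-grid sample.
    """
    p = np.where(mask, np.exp(1j * phi), 0.0)
    f = cidft2(p)
    a = np.abs(f)
    iy, ix = np.unravel_index(int(np.argmax(a)), a.shape)

    def _refine(vals: np.ndarray, i: int) -> float:
        if 0 < i < vals.size - 1:
            denom = vals[i - 1] - 2 * vals[i] + vals[i + 1]
            if denom != 0:
                return i + 0.5 * (vals[i - 1] - vals[i + 1]) / denom
        return float(i)

    py = _refine(a[:, ix], iy)
    px = _refine(a[iy, :], ix)
    ny, nx = phi.shape
    cy, cx = ny // 2, nx // 2
    # pupil tilt a*m shifts the focus by -a n/(2 pi) pixels, so the
    # coefficient is the negated peak offset
    ty = -2 * np.pi * (py - cy) / ny
    tx = -2 * np.pi * (px - cx) / nx
    my = np.arange(ny) - cy
    mx = np.arange(nx) - cx
    tilt = ty * my[:, None] + tx * mx[None, :]
    resid = wrap_phase(phi - tilt)
    piston = np.angle(np.mean(np.exp(1j * resid[mask])))
    resid = np.where(mask, wrap_phase(resid - piston), 0.0)
    return resid, (float(ty), float(tx), float(piston))


def phase_agreement(
    phi_a: np.ndarray, phi_b: np.ndarray, mask: np.ndarray
) -> dict:
    """Compare two pupil phase maps modulo piston and linear tilt.

    Returns circular-aware ``rms_rad`` of the aligned difference and the
    ``pearson`` correlation of the aligned wrapped maps over the mask.
    """
    if phi_a.shape != phi_b.shape or phi_a.shape != mask.shape:
        raise InvalidConfiguration("phase maps and mask must share one grid")
    diff = wrap_phase(phi_b - phi_a)
    resid, (ty, tx, piston) = remove_piston_tilt(diff, mask)
    rms = float(np.sqrt(np.mean(resid[mask] ** 2)))

    # Pearson correlation of the unit-circle embedding (cos, sin) of the
    # aligned maps: circular-aware, 1 for a perfect match, ~0 for
    # independent wrapped maps (plain Pearson on wrapped values is biased by
    # 2 pi flips at the branch cut)
    a = wrap_phase(phi_a)[mask]
    b = wrap_phase(a + resid[mask])
    x = np.concatenate([np.cos(a), np.sin(a)])
    y = np.concatenate([np.cos(b), np.sin(b)])
    if np.std(x) == 0 or np.std(y) == 0:
        pearson = 1.0 if rms < 1e-9 else 0.0
    else:
        pearson = float(np.corrcoef(x, y)[0, 1])
    return {"rms_rad": rms, "pearson": pearson, "tilt": (ty, tx), "piston": piston}


def corrected_strehl(
    truth_phase: np.ndarray, correction: np.ndarray, mask: np.ndarray
) -> float:
    """Strehl of the residual aberration after applying a correction.

    The residual ``truth + correction`` is aligned modulo piston and
    (sub-pixel) tilt — both pure image-shift/global-phase degeneracies —
    before the on-axis pupil average, so a perfect correction up to a shift
    scores 1.
    """
    resid = wrap_phase(truth_phase + correction)
    aligned, _ = remove_piston_tilt(np.where(mask, resid, 0.0), mask)
    return strehl_onaxis(aligned, mask)


def resample_pupil(
    pupil: PupilPhase,
    dk_dst: tuple[float, float],
    shape_dst: tuple[int, int],
    mask_dst: np.ndarray,
) -> PupilPhase:
    """Resample a pupil phase map onto another centered k-grid.

    Interpolates the complex field ``mask exp(i phi)`` bilinearly (phase-safe)
    and returns the wrapped angle on the destination grid.
    """
    src = np.where(pupil.mask, np.exp(1j * pupil.phase), 0.0)
    ny_s, nx_s = src.shape
    ny_d, nx_d = shape_dst
    ky_d = (np.arange(ny_d) - ny_d // 2) * dk_dst[0]
    kx_d = (np.arange(nx_d) - nx_d // 2) * dk_dst[1]
    iy = ky_d / pupil.dk + ny_s // 2
    ix = kx_d / pupil.dk + nx_s // 2
    coords = np.meshgrid(iy, ix, indexing="ij")
    re = map_coordinates(src.real, coords, order=1, mode="constant")
    im = map_coordinates(src.imag, coords, order=1, mode="constant")
    phase = np.angle(re + 1j * im)
    return PupilPhase(
        phase=np.where(mask_dst, phase, 0.0),
        dk=float(dk_dst[0]),
        mask=mask_dst,
        side=pupil.side,
    )


# ---------------------------------------------------------------------------
# single-to-multiple-scattering ratio
# ---------------------------------------------------------------------------


def ssmr_estimate(stack: FieldStack) -> dict:
    """Realised confocal single-to-multiple-scattering intensity ratio.

    Requires a synthetic stack carrying ground truth: the noise-free signal
    frames are re-simulated from the stored object and screens, the noise is
    what remains, and the ratio of mean confocal signal intensity to mean
    noise intensity is measured.  A noise-free stack returns ``inf`` with the
    ``no_noise`` flag set.
    """
    truth = stack.truth
    if "object" not in truth or "patches" not in truth:
        raise InvalidConfiguration("ssmr_estimate needs a stack with /truth")
    if truth.get("noise_sigma2", 0.0) == 0.0:
        return {"ssmr": float("inf"), "no_noise": True}

    from .forward import ObjectMap

    obj = ObjectMap(reflectance=truth["object"], optics=stack.optics)
    patches = [(p["scan_mask"], p["phi_i"], p["phi_o"]) for p in truth["patches"]]
    clean = simulate_scan_patches(
        obj, patches, noise=None,
        scan_y_px=stack.scan_y_px, scan_x_px=stack.scan_x_px,
        fod_px=stack.frame_shape[0],
    )
    cy, cx = stack.frame_shape[0] // 2, stack.frame_shape[1] // 2
    signal_conf = float(np.mean(np.abs(clean.data[:, :, cy, cx]) ** 2))
    noise = stack.data - clean.data
    noise_power = float(np.mean(np.abs(noise) ** 2))
    return {"ssmr": signal_conf / noise_power, "no_noise": False}


def ssmr_estimate_matrix(rm: ReflectionMatrix, exclusion_airy: float = 3.0) -> float:
    """Truth-free estimate from the matrix: confocal excess over background.

    The multiple-scattering background per column is estimated from output
    pixels farther than ``exclusion_airy`` Airy radii from the confocal
    point; the ratio (mean confocal intensity - background) / background is
    returned.  Single scattering spread into the far background biases the
    background slightly high, so this is a lower bound for strongly aberrated
    data.
    """
    opt = rm.optics
    radius_um = exclusion_airy * 0.61 * opt.wavelength / opt.numerical_aperture
    r4 = rm.as4d()
    yy = rm.out_y_px[:, None] * opt.pixel_pitch
    xx = rm.out_x_px[None, :] * opt.pixel_pitch
    conf = np.abs(rm.diagonal()) ** 2
    bgs = []
    for a, sy in enumerate(rm.in_y_px):
        for b, sx in enumerate(rm.in_x_px):
            d2 = (yy - sy * opt.pixel_pitch) ** 2 + (xx - sx * opt.pixel_pitch) ** 2
            far = d2 > radius_um**2
            bgs.append(np.mean(np.abs(r4[:, :, a, b][far]) ** 2))
    bg = float(np.mean(bgs))
    if bg == 0:
        return float("inf")
    return max(float(np.mean(conf)) - bg, 0.0) / bg


def predicted_enhancement(phi_i: PupilPhase, phi_o: PupilPhase) -> float:
    """Confocal intensity gain expected from perfect correction: 1 / (S_i S_o).

    S are on-axis pupil-average Strehls of the injected screens; the round
    trip multiplies the illumination and detection attenuations.
    """
    s_i = strehl_onaxis(phi_i.phase, phi_i.mask)
    s_o = strehl_onaxis(phi_o.phase, phi_o.mask)
    return 1.0 / (s_i * s_o)
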