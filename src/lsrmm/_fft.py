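"""Centered unitary discrete Fourier transforms and k-grid helpers.

All transforms in this package are "centered": the zero-frequency component
and the spatial origin both sit at the central pixel (index ``n // 2``), and
the normalisation is unitary (``norm="ortho"``), so every basis change is
energy-preserving.  Spatial frequencies are in rad/µm throughout.
"""

from __future__ import annotations

import numpy as np


def cdft2(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered unitary 2-D DFT (origin at the central pixel on both sides)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def cidft2(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered unitary 2-D inverse DFT; exact inverse of :func:`cdft2`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def k_axis(n: int, pitch: float) -> np.ndarray:
    """Centered spatial-frequency axis (rad/µm) for ``n`` samples at ``pitch`` µm."""
    return 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(n, d=pitch))


def k_grids(shape: tuple[int, int], pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered (ky, kx) coordinate grids in rad/µm."""
    ky = k_axis(shape[0], pitch)
    kx = k_axis(shape[1], pitch)
    return np.meshgrid(ky, kx, indexing="ij")


def na_mask(shape: tuple[int, int], pitch: float, k_na: float) -> np.ndarray:
    """Boolean disk |k| < k_NA on the centered k-grid.

    The inequality is strict: modes at exactly the NA cutoff coincide with the
    Nyquist ring of a grid sampled at the diffraction limit and would alias.
    """
    kyg, kxg = k_grids(shape, pitch)
    return kyg**2 + kxg**2 < k_na**2


def negate_k(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Map a centered-grid array f(k) to f(-k).

    On an even-sized centered grid index ``m`` carries frequency
    ``(m - n//2) δk``; negation is flip followed by a one-pixel roll, which
    maps the (unpaired) -Nyquist row onto itself.
    """
    out = np.flip(x, axis=axes)
    return np.roll(out, shift=(1, 1), axis=axes)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.angle(np.exp(1j * np.asarray(phi, dtype=float)))
    # np.angle returns [-pi, pi); move -pi to +pi for the documented interval
    out = np.where(out == -np.pi, np.pi, out)
    return out
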