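"""Containers, configuration and deterministic fixtures.

All intermediates live in one HDF5 layout (complex stacks do not fit image
formats); TIFF is used only for human-viewable exports.  Units everywhere:
radians for angles, µm for lengths, rad/µm for spatial frequencies.

File layout (version 1):

    /stack              complex64, dims (scan_y, scan_x, cam_y, cam_x)
    /meta               attrs: wavelength, na, pitch, grid_size, scan axes,
                        frame, seed/ssmr where applicable, format version
    /truth/object       optional ground truth of synthetic stacks
    /truth/patch<i>/    phi_i, phi_o, scan_mask per isoplanatic patch
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from ._fft import negate_k
from .forward import (
    FieldStack,
    InvalidConfiguration,
    NoiseModel,
    ObjectMap,
    OpticsConfig,
    PupilPhase,
    make_filaments,
    make_pupil_phase,
    make_siemens_star,
    simulate_scan,
    simulate_scan_patches,
)

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated end-to-end configuration, serialised into every output."""

    wavelength: float = 0.9
    numerical_aperture: float = 1.0
    grid_size: int = 64
    object_kind: str = "siemens_star"  # siemens_star | filaments | points
    object_params: dict = field(default_factory=dict)
    pupil_model: str = "bandlimited_speckle"
    pupil_params: dict = field(default_factory=lambda: {"n_modes": 500})
    symmetric: bool = True  # enforce phi_i(k) = phi_o(-k) (reciprocity)
    patch_layout: str = "single"  # single | halves
    ssmr: float | None = None
    seed: int = 0
    tol: float = 0.01
    max_iter: int = 50
    subregion: float | None = None  # µm; local correction when set
    margin: float = 0.0  # µm stitching overlap

    def __post_init__(self) -> None:
        OpticsConfig.nyquist(self.wavelength, self.numerical_aperture, self.grid_size)
        if self.ssmr is not None and self.ssmr <= 0:
            raise InvalidConfiguration("ssmr must be positive when set")
        if self.object_kind not in ("siemens_star", "filaments", "points"):
            raise InvalidConfiguration(f"unknown object_kind {self.object_kind!r}")
        if self.patch_layout not in ("single", "halves"):
            raise InvalidConfiguration(f"unknown patch_layout {self.patch_layout!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------


def _write_pupil(grp: h5py.Group, name: str, pupil: PupilPhase) -> None:
    g = grp.create_group(name)
    g.create_dataset("phase", data=pupil.phase.astype(np.float32))
    g.create_dataset("mask", data=pupil.mask)
    g.attrs["dk"] = pupil.dk
    g.attrs["side"] = pupil.side


def _read_pupil(grp: h5py.Group) -> PupilPhase:
    return PupilPhase(
        phase=np.asarray(grp["phase"], dtype=float),
        mask=np.asarray(grp["mask"], dtype=bool),
        dk=float(grp.attrs["dk"]),
        side=str(grp.attrs["side"]),
    )


def write_stack(path: str | Path, stack: FieldStack) -> None:
    """Lossless (complex64) write of a field stack with metadata and truth."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.create_dataset("stack", data=stack.data.astype(np.complex64))
        meta = fh.create_group("meta")
        meta.attrs["wavelength"] = stack.optics.wavelength
        meta.attrs["na"] = stack.optics.numerical_aperture
        meta.attrs["pixel_pitch"] = stack.optics.pixel_pitch
        meta.attrs["grid_size"] = stack.optics.grid_size
        meta.attrs["frame"] = stack.frame
        meta.create_dataset("scan_y_px", data=stack.scan_y_px)
        meta.create_dataset("scan_x_px", data=stack.scan_x_px)
        truth = stack.truth
        if truth:
            tg = fh.create_group("truth")
            if "object" in truth:
                tg.create_dataset("object", data=np.asarray(truth["object"]))
            tg.attrs["noise_sigma2"] = float(truth.get("noise_sigma2", 0.0))
            if "ssmr_requested" in truth:
                tg.attrs["ssmr_requested"] = float(truth["ssmr_requested"])
            for i, patch in enumerate(truth.get("patches", [])):
                pg = tg.create_group(f"patch{i}")
                pg.create_dataset("scan_mask", data=patch["scan_mask"])
                _write_pupil(pg, "phi_i", patch["phi_i"])
                _write_pupil(pg, "phi_o", patch["phi_o"])


def read_stack(path: str | Path) -> FieldStack:
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise InvalidConfiguration(
                f"unsupported container version {version} (expected {FORMAT_VERSION})"
            )
        if "stack" not in fh or "meta" not in fh:
            raise InvalidConfiguration("missing /stack or /meta group")
        meta = fh["meta"]
        optics = OpticsConfig(
            wavelength=float(meta.attrs["wavelength"]),
            numerical_aperture=float(meta.attrs["na"]),
            pixel_pitch=float(meta.attrs["pixel_pitch"]),
            grid_size=int(meta.attrs["grid_size"]),
        )
        truth: dict = {}
        if "truth" in fh:
            tg = fh["truth"]
            if "object" in tg:
                truth["object"] = np.asarray(tg["object"])
            truth["noise_sigma2"] = float(tg.attrs.get("noise_sigma2", 0.0))
            if "ssmr_requested" in tg.attrs:
                truth["ssmr_requested"] = float(tg.attrs["ssmr_requested"])
            patches = []
            i = 0
            while f"patch{i}" in tg:
                pg = tg[f"patch{i}"]
                patches.append(
                    {
                        "scan_mask": np.asarray(pg["scan_mask"], dtype=bool),
                        "phi_i": _read_pupil(pg["phi_i"]),
                        "phi_o": _read_pupil(pg["phi_o"]),
                    }
                )
                i += 1
            if patches:
                truth["patches"] = patches
                if len(patches) == 1:
                    truth["phi_i"] = patches[0]["phi_i"]
                    truth["phi_o"] = patches[0]["phi_o"]
        return FieldStack(
            data=np.asarray(fh["stack"]),
            optics=optics,
            scan_y_px=np.asarray(meta["scan_y_px"]),
            scan_x_px=np.asarray(meta["scan_x_px"]),
            frame=str(meta.attrs["frame"]),
            truth=truth,
        )


def write_result(path: str | Path, result) -> None:
    """Serialise a ClassResult: /phi_i, /phi_o, /R_corrected, /image, /log."""
    import json

    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        _write_pupil(fh, "phi_i", result.phi_i)
        _write_pupil(fh, "phi_o", result.phi_o)
        fh.create_dataset(
            "R_corrected", data=result.spectral_corrected.data.astype(np.complex64)
        )
        fh.create_dataset("image", data=result.image.astype(np.float32))
        fh.attrs["converged"] = bool(result.converged)
        fh.attrs["n_iter"] = int(result.n_iter)
        fh.attrs["log"] = json.dumps(result.log)


def read_result(path: str | Path) -> dict:
    import json

    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise InvalidConfiguration(f"unsupported container version {version}")
        return {
            "phi_i": _read_pupil(fh["phi_i"]),
            "phi_o": _read_pupil(fh["phi_o"]),
            "R_corrected": np.asarray(fh["R_corrected"]),
            "image": np.asarray(fh["image"]),
            "converged": bool(fh.attrs["converged"]),
            "n_iter": int(fh.attrs["n_iter"]),
            "log": json.loads(fh.attrs["log"]),
        }


def export_tiff(path: str | Path, image: np.ndarray) -> None:
    """32-bit float TIFF export (phase in radians or amplitude unitless)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("siemens_star_smallgrid", "two_patch_aniso", "noisy_ssmr008")


def _symmetric_screens(
    optics: OpticsConfig, n_modes: float, seed: int
) -> tuple[PupilPhase, PupilPhase]:
    """One speckle screen and its reciprocity partner phi_o(k) = phi_i(-k)."""
    phi_i = make_pupil_phase(
        optics, "bandlimited_speckle", {"n_modes": n_modes}, seed=seed, side="input"
    )
    phi_o = PupilPhase(
        phase=negate_k(phi_i.phase), dk=phi_i.dk, mask=phi_i.mask, side="output"
    )
    return phi_i, phi_o


def make_fixture(name: str, seed: int = 0) -> dict:
    """Deterministic synthetic datasets used by the tests and the docs.

    ``siemens_star_smallgrid``: 64x64 Siemens star behind a single ~500-mode
    speckle screen pair (reciprocal), no noise.  ``noisy_ssmr008``: same with
    multiple-scattering noise at ssmr = 0.08.  ``two_patch_aniso``: filament
    phantom with independent screens on the left/right halves of the scan
    grid (isoplanatic patches of half the field).
    """
    if name not in FIXTURE_NAMES:
        raise InvalidConfiguration(f"unknown fixture {name!r}")
    optics = OpticsConfig.nyquist(0.9, 1.0, 64)

    if name in ("siemens_star_smallgrid", "noisy_ssmr008"):
        obj = make_siemens_star(16, 64, optics)
        phi_i, phi_o = _symmetric_screens(optics, 500, seed + 1)
        noise = NoiseModel(ssmr=0.08, seed=seed + 7) if name == "noisy_ssmr008" else None
        stack = simulate_scan(obj, phi_i, phi_o, noise=noise)
        return {"stack": stack, "object": obj, "phi_i": phi_i, "phi_o": phi_o,
                "optics": optics, "seed": seed}

    # two_patch_aniso: diffuse filament phantom — myelin-like fibres over a
    # weak diffuse background, all with uniform random per-pixel phase.  The
    # background emulates the speckle-like single-scattered returns of
    # irregular tissue and balances the aberration-retrieval signal between
    # the two isoplanatic patches.
    amp = np.clip(0.3 + 0.7 * make_filaments(12, 2.0, seed + 3, side_px=64), 0, 1)
    rng = np.random.default_rng(seed + 4)
    obj = ObjectMap(
        amp * np.exp(1j * rng.uniform(-np.pi, np.pi, amp.shape)), optics
    )
    phi_i_l, phi_o_l = _symmetric_screens(optics, 250, seed + 11)
    phi_i_r, phi_o_r = _symmetric_screens(optics, 250, seed + 12)
    sy = sx = 32
    left = np.zeros((sy, sx), dtype=bool)
    left[:, : sx // 2] = True
    right = ~left
    stack = simulate_scan_patches(
        obj, [(left, phi_i_l, phi_o_l), (right, phi_i_r, phi_o_r)]
    )
    return {
        "stack": stack, "object": obj, "optics": optics, "seed": seed,
        "screens": {"left": (phi_i_l, phi_o_l), "right": (phi_i_r, phi_o_r)},
        "patch_scan_masks": {"left": left, "right": right},
    }
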