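"""Seeded synthetic B-mode-like phantoms with known ground truth.

The phantom emulates the salient structures of a musculoskeletal ultrasound
scan: a dark speckle background (first-order B-mode speckle amplitude is
classically Rayleigh distributed), a thin hyperechoic bone-surface band, an
acoustic shadow beneath the band (bone transmits almost no sound), and an
optional fracture — a gap in the band where the cortical echo is interrupted.
Each phantom carries a binary ground-truth mask of the gap pixels so that
downstream detection accuracy can be scored exactly.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
``(spec, seed)`` pair reproduces an image bit-for-bit across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "PhantomPair", "simulate_phantom", "degrade"]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic scan.

    Parameters
    ----------
    height, width : int
        Image dimensions in pixels. Row 0 is the shallow (skin) side.
    speckle_scale : float
        Rayleigh scale of the background speckle, in unit-range intensity.
    bone_row : int
        First row of the bone-surface band (0-based).
    bone_brightness : float
        Additive intensity of the hyperechoic band, in [0, 1].
    bone_thickness : int
        Band thickness in pixels.
    shadow_attenuation : float
        Multiplicative factor in (0, 1] applied to every row below the band.
    fracture : bool
        Whether a cortical gap is present.
    gap_center_col, gap_width : int
        Gap geometry (columns); only used when ``fracture`` is set.
    blur_sigma : float
        Default degradation blur used by suite builders (see :func:`degrade`).
    seed : int
        PRNG seed for the speckle field.
    """

    height: int = 192
    width: int = 192
    speckle_scale: float = 0.1
    bone_row: int = 96
    bone_brightness: float = 0.6
    bone_thickness: int = 4
    shadow_attenuation: float = 0.35
    fracture: bool = False
    gap_center_col: int = 96
    gap_width: int = 10
    blur_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if not 0 <= self.bone_row < self.height:
            raise ValueError(f"bone_row {self.bone_row} outside [0, {self.height})")
        if self.bone_thickness < 1:
            raise ValueError("bone_thickness must be >= 1")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be > 0")
        if not 0.0 < self.shadow_attenuation <= 1.0:
            raise ValueError("shadow_attenuation must be in (0, 1]")
        if not 0.0 <= self.bone_brightness <= 1.0:
            raise ValueError("bone_brightness must be in [0, 1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.fracture:
            if self.gap_width < 1:
                raise ValueError("gap_width must be >= 1 when fracture is set")
            lo, hi = self.gap_cols
            if lo < 0 or hi > self.width:
                raise ValueError("fracture gap extends outside the image")

    @property
    def gap_cols(self) -> tuple[int, int]:
        """Half-open column range [lo, hi) of the fracture gap."""
        lo = self.gap_center_col - self.gap_width // 2
        return lo, lo + self.gap_width

    @property
    def band_rows(self) -> tuple[int, int]:
        """Half-open row range [lo, hi) of the bone band."""
        return self.bone_row, min(self.bone_row + self.bone_thickness, self.height)

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PhantomPair:
    """A phantom image together with its fracture-gap ground truth."""

    image: np.ndarray
    truth_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.image.shape != self.truth_mask.shape:
            raise ValueError("image and truth_mask dimensions differ")


def simulate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render a phantom from its spec.

    Background pixels are i.i.d. Rayleigh(``speckle_scale``) clipped to
    [0, 1]; the bone band adds ``bone_brightness`` outside the gap columns;
    all rows below the band are attenuated by ``shadow_attenuation``.
    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    img = rng.rayleigh(scale=spec.speckle_scale, size=(spec.height, spec.width))

    r0, r1 = spec.band_rows
    band = np.zeros((spec.height, spec.width), dtype=bool)
    band[r0:r1, :] = True
    mask = np.zeros_like(band)
    if spec.fracture:
        c0, c1 = spec.gap_cols
        band[r0:r1, c0:c1] = False
        mask[r0:r1, c0:c1] = True
    img[band] += spec.bone_brightness
    img[r1:, :] *= spec.shadow_attenuation
    np.clip(img, 0.0, 1.0, out=img)
    return PhantomPair(image=img, truth_mask=mask.astype(np.uint8))


def degrade(
    image: np.ndarray, blur_sigma: float, noise_sd: float, seed: int
) -> np.ndarray:
    """Gaussian blur then additive Gaussian noise, clipped to [0, 1].

    Models the "before enhancement" acquisition: loss of resolution (blur)
    plus electronic noise. Identity when both parameters are zero. Blur uses
    reflective borders with the kernel truncated at four standard deviations,
    so constant images are invariant.
    """
    if blur_sigma < 0 or noise_sd < 0:
        raise ValueError("blur_sigma and noise_sd must be >= 0")
    out = np.asarray(image, dtype=np.float64)
    if blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=blur_sigma, mode="reflect", truncate=4.0)
    else:
        out = out.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    if blur_sigma == 0 and noise_sd == 0:
        return out
    np.clip(out, 0.0, 1.0, out=out)
    return out
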