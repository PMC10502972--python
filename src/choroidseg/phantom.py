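"""Synthetic layered OCT B-scan phantoms with pixel-perfect choroid ground truth.

A phantom is a stack of horizontal tissue bands drawn column by column:
dark vitreous on top, a bright retinal band whose thickness dips at the
foveal pit, a 2-pixel hyper-reflective RPE line at the bottom of the
retina, a medium-intensity choroid band (optionally pocked with darker
lacunae), and a dim sclera below.  The ground-truth choroid mask is drawn
from the same integer boundary rows as the intensity image, so per-column
mask thickness equals the generating profile exactly; only the intensity
image receives speckle noise and lacunae.

These phantoms are deliberately cartoon-like: they exist so that every
downstream stage (segmentation, post-processing, fovea localization,
thickness measurement) can be exercised and tested without clinical data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BScan",
    "PhantomSpec",
    "generate_phantom",
    "generate_scan_set",
    "BAND_INTENSITIES",
]

# Band reflectivities, anterior to posterior.  Chosen so Otsu separates the
# bright retina+RPE class from everything else; lacunae sit below sclera.
BAND_INTENSITIES = {
    "vitreous": 0.02,
    "retina": 0.65,
    "rpe": 0.95,
    "choroid": 0.30,
    "sclera": 0.15,
    "lacuna": 0.10,
}

#: rows of hyper-reflective RPE at the bottom of the retinal band
#: (counted as part of the retinal thickness profile)
RPE_ROWS = 2


@dataclass
class BScan:
    """One grayscale OCT B-scan: rows are axial depth (row 0 anterior),
    columns are lateral A-scan position."""

    pixels: np.ndarray  # float in [0, 1], shape (rows, cols)
    axial_scale: float = 3.87  # µm per axial pixel
    orientation: str = "horizontal"  # or "vertical"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("BScan requires a single-channel 2-D image")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("BScan intensities must lie in [0, 1]")
        if self.axial_scale <= 0:
            raise ValueError("axial_scale must be positive (µm/pixel)")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError("orientation must be 'horizontal' or 'vertical'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PhantomSpec:
    """Generative parameters for one synthetic B-scan.

    ``retina_thickness_profile`` must have a unique minimum at
    ``fovea_column`` (the pit); ``choroid_thickness_profile`` is the exact
    per-column thickness the ground-truth mask will have.
    """

    height: int
    width: int
    ilm_depth: int  # top retinal surface row, uniform across columns
    retina_thickness_profile: np.ndarray  # int pixels per column
    choroid_thickness_profile: np.ndarray  # int pixels per column
    fovea_column: int
    axial_scale: float = 3.87  # µm / axial pixel; typical SD-OCT pitch
    speckle_sigma: float = 0.0  # multiplicative speckle strength
    lacunae_density: float = 0.0  # expected lacunae per 100 columns, in [0,1]
    seed: int = 0

    def __post_init__(self) -> None:
        self.retina_thickness_profile = np.asarray(
            self.retina_thickness_profile, dtype=int
        )
        self.choroid_thickness_profile = np.asarray(
            self.choroid_thickness_profile, dtype=int
        )
        self.validate()

    def validate(self) -> None:
        ret, cho = self.retina_thickness_profile, self.choroid_thickness_profile
        if ret.shape != (self.width,) or cho.shape != (self.width,):
            raise ValueError("thickness profiles must have one entry per column")
        if self.ilm_depth < 0:
            raise ValueError("ilm_depth must be non-negative")
        if (ret <= 0).any() or (cho <= 0).any():
            raise ValueError("all layer thicknesses must be positive")
        bottom = self.ilm_depth + ret + cho
        if int(bottom.max()) >= self.height:
            raise ValueError(
                f"layer geometry exceeds image height: deepest boundary row "
                f"{int(bottom.max())} >= height {self.height}"
            )
        if not 0 <= self.fovea_column < self.width:
            raise ValueError("fovea_column outside image")
        amin = int(np.argmin(ret))
        if amin != self.fovea_column or (ret == ret[amin]).sum() != 1:
            raise ValueError(
                "fovea_column must be the unique argmin of the retinal profile"
            )
        if self.axial_scale <= 0:
            raise ValueError("axial_scale must be positive")
        if not 0.0 <= self.lacunae_density <= 1.0:
            raise ValueError("lacunae_density must lie in [0, 1]")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be non-negative")

    # ------------------------------------------------------------------ #
    # presets

    @classmethod
    def tiny(
        cls,
        *,
        pit_shift: int = 0,
        choroid_px: int | None = None,
        speckle_sigma: float = 0.06,
        lacunae_density: float = 0.2,
        seed: int = 0,
        axial_scale: float = 3.87,
    ) -> "PhantomSpec":
        """64 x 96 preset sized for CPU tests and desk-scale training."""
        # the pit is deliberately sharp at this scale: at 64 px a smooth
        # pit would round into a flat multi-column tie at the tip
        return cls._preset(
            height=64, width=96, ilm_depth=8,
            retina_base=20, pit_depth=9, pit_sigma=2.5,
            choroid_base=14 if choroid_px is None else choroid_px,
            pit_shift=pit_shift, speckle_sigma=speckle_sigma,
            lacunae_density=lacunae_density, seed=seed, axial_scale=axial_scale,
        )

    @classmethod
    def full(
        cls,
        *,
        pit_shift: int = 0,
        choroid_px: int | None = None,
        speckle_sigma: float = 0.06,
        lacunae_density: float = 0.2,
        seed: int = 0,
        axial_scale: float = 3.87,
    ) -> "PhantomSpec":
        """496 x 768 Spectralis-like preset."""
        return cls._preset(
            height=496, width=768, ilm_depth=110,
            retina_base=95, pit_depth=40, pit_sigma=40.0,
            choroid_base=72 if choroid_px is None else choroid_px,
            pit_shift=pit_shift, speckle_sigma=speckle_sigma,
            lacunae_density=lacunae_density, seed=seed, axial_scale=axial_scale,
        )

    @classmethod
    def _preset(
        cls, *, height, width, ilm_depth, retina_base, pit_depth, pit_sigma,
        choroid_base, pit_shift, speckle_sigma, lacunae_density, seed,
        axial_scale,
    ) -> "PhantomSpec":
        fovea = width // 2 + pit_shift
        cols = np.arange(width)
        pit = pit_depth * np.exp(-((cols - fovea) ** 2) / (2.0 * pit_sigma**2))
        retina = np.round(retina_base - pit).astype(int)
        # rounding can flatten the pit tip into a tie; restore uniqueness
        if (retina == retina[fovea]).sum() > 1:
            retina[fovea] -= 1
        # gentle lateral variation of the choroid, thickest under the fovea
        cho = np.round(
            choroid_base + 2.0 * np.cos((cols - fovea) / width * np.pi)
        ).astype(int)
        return cls(
            height=height, width=width, ilm_depth=ilm_depth,
            retina_thickness_profile=retina, choroid_thickness_profile=cho,
            fovea_column=fovea, axial_scale=axial_scale,
            speckle_sigma=speckle_sigma, lacunae_density=lacunae_density,
            seed=seed,
        )

    @property
    def subfoveal_thickness_px(self) -> int:
        """Ground-truth choroid thickness (pixels) under the fovea."""
        return int(self.choroid_thickness_profile[self.fovea_column])

    @property
    def subfoveal_thickness_um(self) -> float:
        return self.subfoveal_thickness_px * self.axial_scale


def generate_phantom(spec: PhantomSpec) -> tuple[BScan, np.ndarray]:
    """Render a phantom B-scan and its exact ground-truth choroid mask.

    Returns ``(bscan, mask)`` where ``mask`` is uint8 with 1 marking the
    choroid band (the area between the RPE and the chorio-scleral
    boundary).  Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    rows = np.arange(H)[:, None]  # (H, 1) broadcast against columns

    ilm = spec.ilm_depth
    ret = spec.retina_thickness_profile[None, :]
    cho = spec.choroid_thickness_profile[None, :]
    retina_bottom = ilm + ret  # first choroid row
    choroid_bottom = retina_bottom + cho  # first sclera row

    img = np.full((H, W), BAND_INTENSITIES["vitreous"])
    in_retina = (rows >= ilm) & (rows < retina_bottom)
    in_rpe = (rows >= retina_bottom - RPE_ROWS) & (rows < retina_bottom)
    in_choroid = (rows >= retina_bottom) & (rows < choroid_bottom)
    in_sclera = rows >= choroid_bottom
    img[in_retina] = BAND_INTENSITIES["retina"]
    img[in_rpe] = BAND_INTENSITIES["rpe"]
    img[in_choroid] = BAND_INTENSITIES["choroid"]
    img[in_sclera] = BAND_INTENSITIES["sclera"]

    mask = in_choroid.astype(np.uint8)

    # dark lacunae: seeded ellipses fully inside the choroid band
    n_lacunae = rng.binomial(W, spec.lacunae_density / 10.0)
    for _ in range(n_lacunae):
        cx = int(rng.integers(2, W - 2))
        top = int(ilm + spec.retina_thickness_profile[cx])
        thick = int(spec.choroid_thickness_profile[cx])
        if thick < 4:
            continue
        cy = int(rng.integers(top + 1, top + thick - 1))
        ry = max(1, min(int(rng.integers(1, 3)), (thick - 2) // 2))
        rx = int(rng.integers(2, 6))
        ellipse = ((rows - cy) / ry) ** 2 + (
            (np.arange(W)[None, :] - cx) / rx
        ) ** 2 <= 1.0
        img[ellipse & in_choroid] = BAND_INTENSITIES["lacuna"]

    if spec.speckle_sigma > 0:
        img = img * (1.0 + spec.speckle_sigma * rng.standard_normal((H, W)))
    img = np.clip(img, 0.0, 1.0)

    return BScan(img, axial_scale=spec.axial_scale), mask


def generate_scan_set(
    spec: PhantomSpec, jitter_seed: int, jitter_px: int = 2
) -> list[tuple[BScan, np.ndarray]]:
    """Emulate one OCT visit: three horizontal plus three vertical line
    scans through the fovea, each a phantom with a small seeded integer
    jitter (at most ``jitter_px``) added to the choroid profile.

    The per-scan ground-truth subfoveal thickness is recoverable from each
    returned mask, so the six-scan averaging of the thickness measurement
    can be tested exactly.
    """
    rng = np.random.default_rng(jitter_seed)
    scans: list[tuple[BScan, np.ndarray]] = []
    for i in range(6):
        orientation = "horizontal" if i < 3 else "vertical"
        dz = int(rng.integers(-jitter_px, jitter_px + 1)) if jitter_px > 0 else 0
        cho = spec.choroid_thickness_profile + dz
        cho = np.maximum(cho, 1)
        sub = dataclasses.replace(
            spec,
            choroid_thickness_profile=cho,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bscan, mask = generate_phantom(sub)
        bscan.orientation = orientation
        scans.append((bscan, mask))
    return scans
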