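"""From probability maps to subfoveal choroidal thickness.

The measurement chain mirrors clinical practice: threshold the network's
probability map at 0.5, keep only the largest connected component to
discard false positives away from the choroid, locate the fovea as the
thinnest-retina column within the central 25 A-scans (retina segmented by
Otsu thresholding), and read the choroid thickness at that column.  The
subfoveal choroidal thickness (SfChT) for a visit is the mean over the
three horizontal and three vertical line scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .phantom import BScan

__all__ = [
    "ThicknessProfile", "SfChTMeasurement", "binarize", "largest_component",
    "locate_fovea", "thickness_profile", "measure_sfcht", "clean_mask",
]

logger = logging.getLogger(__name__)

#: width (in A-scan columns) of the central search band for the fovea
FOVEA_BAND_WIDTH = 25


def _check_mask(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    return m.astype(np.uint8)


@dataclass
class ThicknessProfile:
    """Per-column choroid thickness in µm; columns with no choroid pixels
    are flagged invalid."""

    thickness_um: np.ndarray
    axial_scale: float
    valid: np.ndarray  # bool per column

    def at(self, column: int) -> float:
        if not self.valid[column]:
            raise ValueError(f"column {column} has no choroid foreground")
        return float(self.thickness_um[column])


@dataclass
class SfChTMeasurement:
    """Per-visit SfChT: one value per line scan plus their mean."""

    subject: str = ""
    visit: str = ""
    per_scan_um: list = field(default_factory=list)
    fovea_columns: list = field(default_factory=list)
    orientations: list = field(default_factory=list)

    @property
    def mean_um(self) -> float:
        return float(np.mean(self.per_scan_um))


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; a pixel is choroid iff p >= threshold
    (inclusive, so an exactly-0.5 probability counts as foreground)."""
    p = np.asarray(p, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return (p >= threshold).astype(np.uint8)


def largest_component(m: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the largest connected foreground component (the
    maximally-connected-domain false-positive filter).

    Ties between equal-size components are broken toward the component
    containing the lexicographically smallest (row, col) pixel.
    """
    m = _check_mask(m)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(m, connectivity=1 if connectivity == 4 else 2)
    n = labels.max()
    if n == 0:
        return np.zeros_like(m)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = int(np.argmax(sizes)) + 1  # argmax: first max wins
    # skimage labels components in raster order, so the first maximal
    # label already contains the lexicographically smallest pixel
    return (labels == best).astype(np.uint8)


def clean_mask(p: np.ndarray, threshold: float = 0.5,
               connectivity: int = 8) -> np.ndarray:
    """Full mask post-processing: binarize, keep the largest component,
    and fill interior holes (lacunae belong to the choroid band)."""
    m = largest_component(binarize(p, threshold), connectivity)
    return ndimage.binary_fill_holes(m).astype(np.uint8)


def locate_fovea(
    b: BScan | np.ndarray,
    band_width: int = FOVEA_BAND_WIDTH,
    choroid_mask: np.ndarray | None = None,
) -> int:
    """Find the foveal A-scan: Otsu-threshold the central ``band_width``
    columns into retina (bright) vs background, count retina pixels per
    column, and return the column with the thinnest retina.

    For an even-width image the band is centred to the left.  Ties are
    broken toward the image centre, then leftward.  If ``choroid_mask``
    is given, counting is restricted to rows above the choroid's top
    boundary in each column.
    """
    img = b.pixels if isinstance(b, BScan) else np.asarray(b, float)
    H, W = img.shape
    if W <= band_width:
        raise ValueError(f"image width {W} must exceed band width {band_width}")
    c0 = (W - band_width) // 2
    band = img[:, c0:c0 + band_width]
    if np.ptp(band) == 0:
        raise ValueError(
            "cannot locate fovea: central band has constant intensity "
            "(Otsu threshold undefined)")
    # Otsu returns the low edge of the inter-class gap when the histogram
    # is strongly bimodal; one isodata refinement (midpoint of the two
    # class means) centres the cut in the gap, which is far more robust
    # to speckle outliers
    thr0 = filters.threshold_otsu(band)
    thr = 0.5 * (band[band <= thr0].mean() + band[band > thr0].mean())
    retina = band > thr
    if choroid_mask is not None:
        cm = _check_mask(choroid_mask)[:, c0:c0 + band_width]
        rows = np.arange(H)[:, None]
        top = np.where(cm.any(axis=0), cm.argmax(axis=0), H)
        retina = retina & (rows < top[None, :])
    counts = retina.sum(axis=0)
    center = (W - 1) / 2.0
    cols = np.arange(c0, c0 + band_width)
    # sort by (count, distance to centre, column index); first wins
    order = np.lexsort((cols, np.abs(cols - center), counts))
    return int(cols[order[0]])


def thickness_profile(m: np.ndarray, axial_scale: float) -> ThicknessProfile:
    """Per-column choroid thickness: foreground pixel count x axial pitch."""
    m = _check_mask(m)
    if axial_scale <= 0:
        raise ValueError("axial_scale must be positive (µm/pixel)")
    counts = m.sum(axis=0)
    return ThicknessProfile(
        thickness_um=counts * float(axial_scale),
        axial_scale=float(axial_scale),
        valid=counts > 0,
    )


def measure_sfcht(
    scans: list[tuple[BScan, np.ndarray]],
    subject: str = "",
    visit: str = "",
    band_width: int = FOVEA_BAND_WIDTH,
) -> SfChTMeasurement:
    """Measure SfChT from up to six (B-scan, choroid mask) pairs and
    average over the scans.

    A scan whose subfoveal column contains no choroid foreground is
    excluded with a logged warning; if every scan is excluded the
    measurement is rejected.
    """
    if not 1 <= len(scans) <= 6:
        raise ValueError("measure_sfcht expects between 1 and 6 scans")
    result = SfChTMeasurement(subject=subject, visit=visit)
    for i, (bscan, mask) in enumerate(scans):
        col = locate_fovea(bscan, band_width=band_width, choroid_mask=mask)
        profile = thickness_profile(mask, bscan.axial_scale)
        if not profile.valid[col]:
            logger.warning(
                "scan %d (%s): no choroid at subfoveal column %d; excluded",
                i, bscan.orientation, col)
            continue
        result.per_scan_um.append(profile.at(col))
        result.fovea_columns.append(col)
        result.orientations.append(bscan.orientation)
    if not result.per_scan_um:
        raise ValueError("all scans excluded: no valid subfoveal thickness")
    return result
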