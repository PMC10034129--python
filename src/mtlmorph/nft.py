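"""Detection of tangle-like objects on sections and density measurement.

A pluggable per-pixel detector produces a probability map (default: a
normalized Laplacian-of-Gaussian blob response through a logistic); instances
are delineated by thresholding, peak seeding and watershed; densities are
counts per mm^2 of Otsu-segmented foreground tissue, with per-stack
calibration from replicate-section count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .projective import SectionImage


@dataclass
class Detection:
    y_px: float
    x_px: float
    area_px: int


@dataclass
class DetectionSet:
    """Detections on one section, in pixel and mm coordinates."""

    section_id: int
    detections: List[Detection]
    pixel_size: float
    detector_id: str = "log-blob"

    @property
    def count(self) -> int:
        return len(self.detections)

    def centroids_px(self) -> np.ndarray:
        if not self.detections:
            return np.zeros((0, 2))
        return np.array([[d.y_px, d.x_px] for d in self.detections])

    def centroids_mm(self) -> np.ndarray:
        return self.centroids_px() * self.pixel_size


@dataclass
class DensityRecord:
    section_id: int
    region: str
    count: int
    tissue_area_mm2: float
    density_per_mm2: float
    calibration_scale: float = 1.0


# ---------------------------------------------------------------------------
# probability maps (pluggable detector registry)

_DETECTORS: Dict[str, Callable] = {}


def register_detector(name: str, fn: Callable[[np.ndarray], np.ndarray]):
    """Register a per-pixel probability detector: image -> map in [0, 1].

    An externally trained model (e.g. a network) can be plugged in by wrapping
    its inference call; the default is a classical blob detector.
    """
    _DETECTORS[name] = fn


def log_blob_detector(blob_sigma_px: float = 1.2, gain: float = 25.0,
                      offset: float = 0.27) -> Callable[[np.ndarray], np.ndarray]:
    """Scale-normalized negative Laplacian-of-Gaussian response mapped through
    a logistic; responds to compact bright peaks at the given scale."""

    def detect(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, float)
        resp = -blob_sigma_px ** 2 * ndi.gaussian_laplace(img, blob_sigma_px)
        # normalize by the tissue/background contrast gap: peaks are scored
        # relative to the stain contrast, which is stable across sections
        # and independent of how many objects a section happens to carry
        # (noise- or spread-based scales drift with object load)
        if np.ptp(img) > 0:
            t = threshold_otsu(img)
            fg = img > t
            gap = float(img[fg].mean() - img[~fg].mean()) if fg.any() and (~fg).any() \
                else float(np.ptp(img))
        else:
            gap = 1.0
        z = resp / max(gap, 1e-12)
        return 1.0 / (1.0 + np.exp(-gain * (z - offset)))

    return detect


register_detector("log-blob", log_blob_detector())
# offset: contrast-relative threshold midway between the background/texture
# response ceiling and the faintest compact-peak response on blob sections


def probability_map(section: SectionImage, detector: "str | Callable" = "log-blob"
                    ) -> np.ndarray:
    fn = _DETECTORS[detector] if isinstance(detector, str) else detector
    p = np.asarray(fn(section.image), float)
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# foreground segmentation


def foreground_mask(section: SectionImage, polarity: str = "bright"):
    """Otsu foreground-tissue mask and its area in mm^2.

    ``polarity='bright'`` keeps above-threshold pixels; 'dark' the converse
    (for inverted-contrast stains).
    """
    img = section.image
    if np.ptp(img) == 0:
        import warnings
        warnings.warn("constant section image: empty foreground")
        return np.zeros(img.shape, bool), 0.0
    t = threshold_otsu(img)
    mask = img > t if polarity == "bright" else img < t
    area = float(mask.sum()) * section.pixel_size ** 2
    return mask, area


# ---------------------------------------------------------------------------
# instance segmentation


def instance_segment(prob_map: np.ndarray, pixel_size: float = 1.0,
                     section_id: int = 0, p_min: float = 0.5,
                     min_separation_px: int = 2, min_area_px: int = 2
                     ) -> DetectionSet:
    """Watershed delineation of individual objects in a probability map.

    Seeds are local maxima above ``p_min`` separated by at least
    ``min_separation_px``; touching objects are split by watershed on the
    negated map; objects smaller than ``min_area_px`` are discarded.
    """
    p = np.asarray(prob_map, float)
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probability map must lie in [0, 1]")
    above = p >= p_min
    dets: List[Detection] = []
    if above.any():
        seeds = peak_local_max(p, min_distance=min_separation_px,
                               threshold_abs=p_min, exclude_border=False)
        if len(seeds):
            markers = np.zeros(p.shape, dtype=np.int32)
            markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
            lab = watershed(-p, markers=markers, mask=above)
            for i in range(1, len(seeds) + 1):
                sel = lab == i
                area = int(sel.sum())
                if area < min_area_px:
                    continue
                ys, xs = np.nonzero(sel)
                w = p[sel]
                dets.append(Detection(float(np.average(ys, weights=w)),
                                      float(np.average(xs, weights=w)), area))
    return DetectionSet(section_id, dets, pixel_size)


# ---------------------------------------------------------------------------
# density


def density(detections: DetectionSet, fg_mask: np.ndarray,
            region_labels: np.ndarray, pixel_size: float,
            region_names: Optional[Dict[int, str]] = None,
            calibration_scale: float = 1.0) -> List[DensityRecord]:
    """Per-region NFT densities: centroid-in-region counts divided by the
    region's foreground tissue area (mm^2).  Regions with zero foreground
    area are suppressed (with a note via warnings)."""
    region_labels = np.asarray(region_labels)
    if region_labels.shape != fg_mask.shape:
        raise ValueError("label and mask grids must match")
    cents = detections.centroids_px()
    labels_at = np.zeros(len(cents), dtype=np.int64)
    if len(cents):
        iy = np.clip(np.round(cents[:, 0]).astype(int), 0, fg_mask.shape[0] - 1)
        ix = np.clip(np.round(cents[:, 1]).astype(int), 0, fg_mask.shape[1] - 1)
        labels_at = region_labels[iy, ix]
    area_px = pixel_size ** 2
    records = []
    for rid in np.unique(region_labels[region_labels > 0]):
        area = float(np.sum(fg_mask & (region_labels == rid))) * area_px
        cnt = int(np.sum(labels_at == rid))
        if area <= 0:
            import warnings
            warnings.warn(f"region {rid} has zero foreground area; record suppressed")
            continue
        name = region_names.get(int(rid), str(rid)) if region_names else str(rid)
        records.append(DensityRecord(detections.section_id, name, cnt, area,
                                     calibration_scale * cnt / area,
                                     calibration_scale))
    return records


# ---------------------------------------------------------------------------
# cross-stack calibration


def calibrate_and_normalize(density_tables: Dict[str, pd.DataFrame],
                            replicate_counts: Optional[Dict[str, Sequence[tuple]]] = None
                            ) -> Dict[str, pd.DataFrame]:
    """Normalize per-stack densities to [0, 1] with optional replicate-ratio
    calibration.

    ``replicate_counts[stack]`` is a sequence of (original, replicate) count
    pairs per section; the stack scale is the mean per-section ratio
    original/replicate, and calibrated density = density / scale.  Sections
    with a zero replicate count are skipped.  Each stack is then mapped to
    [0, 1] by its own maximum, which preserves the within-stack ordering.
    """
    out = {}
    for stack, df in density_tables.items():
        df = df.copy()
        scale = 1.0
        if replicate_counts and stack in replicate_counts:
            ratios = [o / r for o, r in replicate_counts[stack] if r > 0]
            if not ratios:
                raise ValueError(f"no usable replicate pairs for stack {stack}")
            scale = float(np.mean(ratios))
        df["calibrated_density"] = df["density_per_mm2"] / scale
        mx = df["calibrated_density"].max()
        df["normalized_density"] = (df["calibrated_density"] / mx if mx > 0
                                    else 0.0)
        df["calibration_scale"] = scale
        out[stack] = df
    return out


def replicate_ratio(original_counts: Sequence[float],
                    replicate_counts: Sequence[float]) -> float:
    """Mean per-section original/replicate detection-count ratio."""
    ratios = [o / r for o, r in zip(original_counts, replicate_counts) if r > 0]
    if not ratios:
        raise ValueError("no sections with nonzero replicate counts")
    return float(np.mean(ratios))
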