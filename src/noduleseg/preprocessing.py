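"""Lung-field extraction from a CT slice.

The chain: optional Hounsfield clamp, standardization, median filtering,
Perona-Malik anisotropic diffusion, 1-D K-means intensity clustering with
thresholding (dark clusters become the air/lung candidate mask),
morphological opening, connected-component lung-region selection, and
multiplication of the (dilated) lung mask with the slice to produce the ROI.
Nodule ground truth is rasterized from multi-reader contour annotations by
per-pixel consensus voting.

Standard steps delegate to scipy.ndimage, scikit-image and scikit-learn;
the diffusion filter is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as _draw
from skimage import measure as _measure
from sklearn.cluster import KMeans


class PreprocessingError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class DegenerateInputError(ValueError):
    """Input lacks the variation the operation requires (e.g. constant image)."""


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: disk, square (side 2r+1) or cross."""

    shape: str = "disk"
    radius: int = 1

    def __post_init__(self):
        if self.shape not in ("disk", "square", "cross"):
            raise ValueError("shape must be one of disk, square, cross")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")

    def footprint(self) -> np.ndarray:
        r = self.radius
        size = 2 * r + 1
        if self.shape == "square":
            return np.ones((size, size), dtype=bool)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        if self.shape == "disk":
            return xx**2 + yy**2 <= r**2
        return (xx == 0) | (yy == 0)  # cross


@dataclass(frozen=True)
class DiffusionParams:
    """Perona-Malik parameters; gamma <= 0.25 is the 4-neighbour stability bound."""

    n_iterations: int = 10
    kappa: float = 30.0
    gamma: float = 0.1
    conduction: str = "exponential"

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 < self.gamma <= 0.25:
            raise ValueError("gamma must lie in (0, 0.25] for stability")
        if self.conduction not in ("exponential", "rational"):
            raise ValueError("conduction must be 'exponential' or 'rational'")


@dataclass(frozen=True)
class RegionCriteria:
    """Connected-component selection rule for the lung fields."""

    min_area_fraction: float = 0.005
    border_margin: int = 2
    max_regions: int = 2
    fill_holes: bool = True
    closing_radius: int = 5

    def __post_init__(self):
        if not 0 <= self.min_area_fraction < 1:
            raise ValueError("min_area_fraction must lie in [0, 1)")
        if self.border_margin < 0 or self.max_regions < 1:
            raise ValueError("border_margin >= 0 and max_regions >= 1 required")


@dataclass
class PreprocessConfig:
    hu_input: bool = False
    hu_clip: tuple[float, float] = (-1000.0, 400.0)
    median_window: int = 3
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    kmeans_k: int = 2
    kmeans_seed: int = 0
    opening_selem: StructuringElement = field(
        default_factory=lambda: StructuringElement("disk", 2))
    region_criteria: RegionCriteria = field(default_factory=RegionCriteria)
    dilation_selem: StructuringElement = field(
        default_factory=lambda: StructuringElement("disk", 5))


# --------------------------------------------------------------------------
# intensity operations
# --------------------------------------------------------------------------
def standardize(image: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-(population)-std rescaling."""
    img = np.asarray(image, dtype=np.float64)
    std = img.std()
    if std == 0:
        raise DegenerateInputError("constant image cannot be standardized")
    return (img - img.mean()) / std


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Window-median smoothing with reflected borders."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    return ndimage.median_filter(np.asarray(image, dtype=float),
                                 size=window, mode="reflect")


def anisotropic_diffusion(image: np.ndarray,
                          params: DiffusionParams | None = None) -> np.ndarray:
    """Perona-Malik edge-preserving diffusion.

    Explicit 4-neighbour updates with zero-flux (replicated) borders and the
    chosen conduction function: exponential ``exp(-(d/kappa)^2)`` or rational
    ``1 / (1 + (d/kappa)^2)``.
    """
    params = params or DiffusionParams()
    img = np.asarray(image, dtype=np.float64).copy()
    k2 = params.kappa**2
    for _ in range(params.n_iterations):
        padded = np.pad(img, 1, mode="edge")
        dn = padded[:-2, 1:-1] - img
        ds = padded[2:, 1:-1] - img
        de = padded[1:-1, 2:] - img
        dw = padded[1:-1, :-2] - img
        if params.conduction == "exponential":
            flux = sum(d * np.exp(-(d**2) / k2) for d in (dn, ds, de, dw))
        else:
            flux = sum(d / (1.0 + d**2 / k2) for d in (dn, ds, de, dw))
        img += params.gamma * flux
    return img


def kmeans_threshold(image: np.ndarray, k: int = 2, seed: int = 0) -> np.ndarray:
    """1-D K-means on pixel intensities; dark clusters become 1.

    Clusters are split at the midpoint of the largest gap between sorted
    centroids; pixels in clusters below the threshold (air and lung
    parenchyma on CT) are labeled 1.  Deterministic given the seed.
    """
    img = np.asarray(image, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    values = img.reshape(-1, 1)
    if np.unique(values).size < k:
        raise DegenerateInputError(
            f"image has fewer than k={k} distinct intensities"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(values)
    centers = km.cluster_centers_.reshape(-1)
    order = np.argsort(centers)
    sorted_centers = centers[order]
    gaps = np.diff(sorted_centers)
    split = int(np.argmax(gaps))
    thresh = 0.5 * (sorted_centers[split] + sorted_centers[split + 1])
    dark = centers < thresh
    mask = dark[km.labels_].reshape(img.shape)
    return mask.astype(np.uint8)


# --------------------------------------------------------------------------
# morphology
# --------------------------------------------------------------------------
def _check_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    return m.astype(bool)


def _check_selem(selem: StructuringElement) -> np.ndarray:
    fp = selem.footprint()
    if not fp.any():
        raise ValueError("structuring element is empty")
    return fp


def erode(mask: np.ndarray, selem: StructuringElement) -> np.ndarray:
    """Binary erosion; pixels outside the image count as 0."""
    m = _check_binary(mask)
    fp = _check_selem(selem)
    return ndimage.binary_erosion(m, structure=fp, border_value=0).astype(np.uint8)


def dilate(mask: np.ndarray, selem: StructuringElement) -> np.ndarray:
    m = _check_binary(mask)
    fp = _check_selem(selem)
    return ndimage.binary_dilation(m, structure=fp, border_value=0).astype(np.uint8)


def morphological_open(mask: np.ndarray, selem: StructuringElement) -> np.ndarray:
    """Opening: erosion followed by dilation with the same element."""
    return dilate(erode(mask, selem), selem)


# --------------------------------------------------------------------------
# region selection and masking
# --------------------------------------------------------------------------
def select_lung_regions(mask: np.ndarray,
                        criteria: RegionCriteria | None = None) -> np.ndarray:
    """Keep the largest interior connected components (8-connectivity).

    Components whose bounding box comes within ``border_margin`` pixels of
    the image border (the air surrounding the body) or whose area is below
    ``min_area_fraction`` of the image are discarded; of the survivors the
    ``max_regions`` largest are kept.
    """
    criteria = criteria or RegionCriteria()
    m = _check_binary(mask)
    h, w = m.shape
    labels = _measure.label(m, connectivity=2)
    min_area = criteria.min_area_fraction * m.size
    margin = criteria.border_margin
    candidates = []
    for region in _measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        touches = r0 < margin or c0 < margin or r1 > h - margin or c1 > w - margin
        if touches or region.area < min_area:
            continue
        candidates.append((region.area, region.label))
    if not candidates:
        warnings.warn("no lung region survived selection; returning empty mask")
        return np.zeros_like(m, dtype=np.uint8)
    candidates.sort(reverse=True)
    keep = {lab for _, lab in candidates[: criteria.max_regions]}
    selected = np.isin(labels, list(keep))
    if criteria.closing_radius > 0:
        # nodules near the pleural boundary cut bays into the intensity-based
        # candidate mask; a closing smooths them back into the lung region
        fp = StructuringElement("disk", criteria.closing_radius).footprint()
        selected = ndimage.binary_closing(selected, structure=fp, border_value=0)
    if criteria.fill_holes:
        # interior nodules are brighter than parenchyma and punch holes into
        # the candidate mask; the lung ROI must contain them
        selected = ndimage.binary_fill_holes(selected)
    return selected.astype(np.uint8)


def apply_lung_mask(image: np.ndarray, lung_mask: np.ndarray,
                    dilation_selem: StructuringElement | None = None) -> np.ndarray:
    """Dilate the lung mask, then multiply it with the slice (non-lung -> 0)."""
    img = np.asarray(image, dtype=float)
    if img.shape != np.asarray(lung_mask).shape:
        raise ValueError("image and lung mask shapes differ")
    mask = (dilate(lung_mask, dilation_selem)
            if dilation_selem is not None else _check_binary(lung_mask).astype(np.uint8))
    return img * mask


# --------------------------------------------------------------------------
# annotation rasterization
# --------------------------------------------------------------------------
def rasterize_annotations(annotations, shape: tuple[int, int],
                          consensus_fraction: float = 0.5,
                          min_diameter_mm: float = 3.0) -> np.ndarray:
    """Consensus nodule mask from per-reader contours.

    Each reader's (sufficiently large) contours are filled to a binary map;
    a pixel becomes nodule when at least ``consensus_fraction`` of readers
    marked it.  Contours with equivalent diameter below ``min_diameter_mm``
    are excluded before voting (per reader, per nodule).
    """
    if not 0 < consensus_fraction <= 1:
        raise ValueError("consensus_fraction must lie in (0, 1]")
    readers = annotations.readers
    if not readers:
        return np.zeros(shape, dtype=np.uint8)
    votes = np.zeros(shape, dtype=np.int32)
    for reader in readers:
        reader_map = np.zeros(shape, dtype=bool)
        for contour in reader.contours:
            if contour.equivalent_diameter_mm < min_diameter_mm:
                continue
            pts = np.asarray(contour.points, dtype=float)
            if np.any(pts < 0) or np.any(pts[:, 0] >= shape[0]) or np.any(pts[:, 1] >= shape[1]):
                raise ValueError("contour extends outside image bounds")
            rr, cc = _draw.polygon(pts[:, 0], pts[:, 1], shape=shape)
            reader_map[rr, cc] = True
        votes += reader_map
    return (votes >= consensus_fraction * len(readers)).astype(np.uint8)


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------
def preprocess_slice(image: np.ndarray,
                     config: PreprocessConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Run the full lung-extraction chain on one slice.

    Returns ``(roi, lung_mask)``: the slice restricted to the (dilated) lung
    fields and the selected (undilated) lung mask.  Stage failures are
    re-raised as :class:`PreprocessingError` naming the stage.
    """
    config = config or PreprocessConfig()
    img = np.asarray(image, dtype=float)

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise PreprocessingError(f"stage '{name}': {exc}") from exc

    if config.hu_input:
        img = np.clip(img, *config.hu_clip)
    std = stage("standardize", standardize, img)
    med = stage("median_filter", median_filter, std, config.median_window)
    dif = stage("anisotropic_diffusion", anisotropic_diffusion, med, config.diffusion)
    km = stage("kmeans_threshold", kmeans_threshold, dif, config.kmeans_k,
               config.kmeans_seed)
    opened = stage("morphological_open", morphological_open, km, config.opening_selem)
    lung_mask = stage("select_lung_regions", select_lung_regions, opened,
                      config.region_criteria)
    roi = stage("apply_lung_mask", apply_lung_mask, img, lung_mask,
                config.dilation_selem)
    return roi, lung_mask
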