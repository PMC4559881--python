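"""Brightfield amyloid-plaque and fluorescence glia-cluster quantification.

Re-usable implementation of a classical H-DAB histology pipeline:

1. color deconvolution of the RGB section image into hematoxylin
   (nuclear counterstain) and DAB (Aβ immunostain) optical densities;
2. nuclei detection on the hematoxylin channel and construction of a
   dilated exclusion zone around nuclei;
3. adaptive (mean-offset local) thresholding of the DAB channel,
   removal of exclusion-zone pixels and of sub-granule specks;
4. size- and nuclear-proximity-based classification of the remaining
   deposits into intracellular granules (25–200 px or within nuclear
   vicinity), small plaques (200–1000 px, detached from nuclei) and
   large plaques (> 1000 px);
5. ROI area fraction, glia (GFAP/Iba1) cluster counting on
   single-channel fluorescence images, and plaque–glia correlation.

All pixel-area thresholds are defined at the pipeline's native export
scale; :func:`scale_thresholds` converts them when the pixel size
differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage import color, filters, measure, morphology

#: deposit size-class boundaries in pixels (closed upper bounds)
GRANULE_MIN_PX = 25
INTRACELLULAR_MAX_PX = 200
SMALL_PLAQUE_MAX_PX = 1000

CATEGORIES = ("rejected", "intracellular", "small_plaque", "large_plaque")


class ImagingError(ValueError):
    pass


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop connected components with fewer than ``min_area`` pixels."""
    return morphology.remove_small_objects(mask, max_size=min_area - 1)


def scale_thresholds(pixel_size_um: float, native_pixel_size_um: float) -> dict:
    """Rescale the pixel-area class boundaries to a different pixel size."""
    f = (native_pixel_size_um / pixel_size_um) ** 2
    return {
        "granule_min_px": GRANULE_MIN_PX * f,
        "intracellular_max_px": INTRACELLULAR_MAX_PX * f,
        "small_plaque_max_px": SMALL_PLAQUE_MAX_PX * f,
    }


# ---------------------------------------------------------------------------
# color deconvolution
# ---------------------------------------------------------------------------

def color_deconvolve(image: np.ndarray, stain_matrix: np.ndarray | None = None):
    """Separate an RGB brightfield image into hematoxylin and DAB OD channels.

    Uses optical-density unmixing with the standard H-DAB stain vectors
    by default (``stain_matrix`` rows are RGB absorbance directions for
    hematoxylin, DAB and a residual).  Negative unmixed densities are
    clipped to 0 and saturated black pixels never produce NaN.

    Returns ``(hematoxylin_od, dab_od)``.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ImagingError("expected an RGB image (H, W, 3)")
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    else:
        img = img.astype(float)
    conv = color.hdx_from_rgb if stain_matrix is None else np.linalg.inv(stain_matrix)
    stains = color.separate_stains(img, conv)
    stains = np.nan_to_num(stains, nan=0.0, posinf=0.0, neginf=0.0)
    stains = np.clip(stains, 0.0, None)
    return stains[..., 0], stains[..., 1]


def recombine_stains(hema_od: np.ndarray, dab_od: np.ndarray) -> np.ndarray:
    """Rebuild the RGB image from H-DAB OD channels (reconstruction check)."""
    stack = np.stack([hema_od, dab_od, np.zeros_like(hema_od)], axis=-1)
    return color.combine_stains(stack, color.rgb_from_hdx)


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleiDetection:
    mask: np.ndarray            #: boolean nuclei mask
    exclusion: np.ndarray       #: nuclei dilated by the exclusion radius
    n_nuclei: int


def detect_nuclei(
    hematoxylin_od: np.ndarray,
    threshold: float | None = None,
    min_size: int = 30,
    exclusion_radius: int = 5,
    min_signal: float = 0.05,
) -> NucleiDetection:
    """Detect nuclei on the hematoxylin OD channel.

    Otsu threshold (unless given), hole filling and a minimum-size
    filter; the exclusion zone is the mask dilated by
    ``exclusion_radius``.  A blank channel yields an empty mask rather
    than an error.
    """
    od = np.asarray(hematoxylin_od, dtype=float)
    if od.max() < min_signal:
        empty = np.zeros(od.shape, dtype=bool)
        return NucleiDetection(mask=empty, exclusion=empty.copy(), n_nuclei=0)
    thr = filters.threshold_otsu(od) if threshold is None else threshold
    mask = od > thr
    mask = ndimage.binary_fill_holes(mask)
    mask = _remove_small(mask, min_size)
    exclusion = morphology.dilation(mask, morphology.disk(exclusion_radius))
    n = int(measure.label(mask, connectivity=2).max())
    return NucleiDetection(mask=mask, exclusion=exclusion, n_nuclei=n)


# ---------------------------------------------------------------------------
# deposit segmentation and classification
# ---------------------------------------------------------------------------

def segment_deposits(
    dab_od: np.ndarray,
    nuclei_exclusion: np.ndarray | None = None,
    block_size: int = 101,
    offset: float = 0.05,
    min_od: float = 0.15,
    min_area_px: int = GRANULE_MIN_PX,
) -> np.ndarray:
    """Segment DAB-positive deposits with a mean-offset local threshold.

    A pixel is a candidate when its DAB OD exceeds both the local mean
    over a ``block_size`` window plus ``offset`` and the global floor
    ``min_od``.  Pixels inside the nuclei exclusion zone are removed
    before labeling; connected components (8-connectivity) smaller than
    ``min_area_px`` are rejected as unspecific granular noise.

    Returns the labeled image (0 = background).
    """
    od = np.asarray(dab_od, dtype=float)
    local = filters.threshold_local(od, block_size=block_size, method="mean",
                                    offset=-offset)
    mask = od > np.maximum(local, min_od)
    if nuclei_exclusion is not None:
        mask &= ~nuclei_exclusion
    mask = _remove_small(mask, min_area_px)
    return measure.label(mask, connectivity=2)


@dataclass(frozen=True)
class DepositObject:
    """One segmented deposit with its size class."""

    label: int
    area_px: int
    centroid: tuple[float, float]   #: (row, col)
    category: str
    near_nucleus: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ImagingError(f"unknown category {self.category!r}")


def classify_area(area_px: int, near_nucleus: bool) -> str:
    """Size-class rule for one deposit.

    Large plaques are > 1000 px irrespective of nuclear proximity;
    200–1000 px objects are small plaques unless within nuclear
    vicinity (then intracellular); 25–200 px objects are intracellular;
    anything smaller is rejected as granular noise.
    """
    if area_px > SMALL_PLAQUE_MAX_PX:
        return "large_plaque"
    if area_px > INTRACELLULAR_MAX_PX:
        return "intracellular" if near_nucleus else "small_plaque"
    if area_px >= GRANULE_MIN_PX:
        return "intracellular"
    return "rejected"


def classify_deposits(
    labels: np.ndarray,
    nuclei_mask: np.ndarray | None = None,
    vicinity_radius: float = 10.0,
) -> list[DepositObject]:
    """Classify labeled deposits into the three size categories.

    ``near_nucleus`` is true when the minimum distance from any object
    pixel to the nuclei mask is at most ``vicinity_radius`` pixels.
    """
    if nuclei_mask is not None and nuclei_mask.any():
        dist = ndimage.distance_transform_edt(~np.asarray(nuclei_mask, dtype=bool))
    else:
        dist = None
    out = []
    for region in measure.regionprops(labels):
        if dist is None:
            near = False
        else:
            rr, cc = region.coords[:, 0], region.coords[:, 1]
            near = bool(dist[rr, cc].min() <= vicinity_radius)
        out.append(
            DepositObject(
                label=int(region.label),
                area_px=int(region.area),
                centroid=tuple(map(float, region.centroid)),
                category=classify_area(int(region.area), near),
                near_nucleus=near,
            )
        )
    return out


def category_counts(objects: list[DepositObject]) -> dict:
    counts = {c: 0 for c in CATEGORIES}
    for o in objects:
        counts[o.category] += 1
    return counts


def area_fraction(
    labels: np.ndarray,
    roi_mask: np.ndarray,
    objects: list[DepositObject] | None = None,
    categories: tuple[str, ...] = ("intracellular", "small_plaque", "large_plaque"),
) -> float:
    """Percent of ROI pixels covered by retained deposits.

    By default all three retained categories count toward the stained
    area; pass a subset of ``categories`` to restrict (e.g. plaques
    only).  Raises on an empty ROI.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ImagingError("ROI mask is empty")
    if objects is None:
        deposit = (labels > 0) & roi
    else:
        keep = {o.label for o in objects if o.category in categories}
        deposit = np.isin(labels, sorted(keep)) & roi
    return 100.0 * float(deposit.sum()) / float(roi.sum())


# ---------------------------------------------------------------------------
# glia clusters and pathology correlation
# ---------------------------------------------------------------------------

def count_glia_clusters(
    channel_image: np.ndarray,
    roi_mask: np.ndarray,
    min_area_px: int = 20,
    threshold: float | None = None,
) -> int:
    """Count marker-positive cell clusters in a fluorescence channel.

    Otsu threshold computed within the ROI, connected components
    (8-connectivity) of at least ``min_area_px`` pixels are counted.
    The count is invariant to rescaling the intensities by a positive
    constant.  A blank (constant) channel counts zero clusters.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ImagingError("ROI mask is empty")
    img = np.asarray(channel_image, dtype=float)
    vals = img[roi]
    if np.ptp(vals) == 0:
        return 0
    thr = filters.threshold_otsu(vals) if threshold is None else threshold
    mask = (img > thr) & roi
    mask = _remove_small(mask, min_area_px)
    return int(measure.label(mask, connectivity=2).max())


@dataclass(frozen=True)
class PathologyCorrelation:
    """Linear association between per-animal plaque burden and glia clusters."""

    r_squared: float
    p_value: float        #: two-sided p for Pearson's r
    slope: float
    intercept: float
    x_grid: np.ndarray
    ci_lower: np.ndarray  #: pointwise 95 % CI band of the fitted mean
    ci_upper: np.ndarray


def correlate_pathology(x, y, ci_points: int = 100) -> PathologyCorrelation:
    """Pearson correlation and linear fit of glia clusters on plaque area.

    Returns r², two-sided p-value, the least-squares line and a
    pointwise 95 % confidence band for the fitted mean response.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ImagingError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ImagingError("zero variance in x or y")
    fit = stats.linregress(x, y)
    n = x.size
    resid = y - (fit.intercept + fit.slope * x)
    s2 = float(resid @ resid) / (n - 2)
    grid = np.linspace(x.min(), x.max(), ci_points)
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_mean = np.sqrt(s2 * (1.0 / n + (grid - x.mean()) ** 2 / sxx))
    tcrit = stats.t.ppf(0.975, n - 2)
    line = fit.intercept + fit.slope * grid
    return PathologyCorrelation(
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        x_grid=grid,
        ci_lower=line - tcrit * se_mean,
        ci_upper=line + tcrit * se_mean,
    )


# ---------------------------------------------------------------------------
# end-to-end section quantification
# ---------------------------------------------------------------------------

@dataclass
class SectionQuantification:
    """Per-section summary: counts per category, area fraction, glia counts."""

    area_fraction_pct: float
    counts: dict
    glia_clusters: dict = field(default_factory=dict)
    objects: list = field(default_factory=list)


def quantify_section(
    image: np.ndarray,
    roi_mask: np.ndarray,
    gfap: np.ndarray | None = None,
    iba1: np.ndarray | None = None,
    exclusion_radius: int = 5,
    vicinity_radius: float = 10.0,
    glia_min_area_px: int = 20,
    **segment_kwargs,
) -> SectionQuantification:
    """Run the full plaque pipeline on one RGB section image."""
    hema, dab = color_deconvolve(image)
    nuclei = detect_nuclei(hema, exclusion_radius=exclusion_radius)
    labels = segment_deposits(dab, nuclei.exclusion, **segment_kwargs)
    objects = classify_deposits(labels, nuclei.mask, vicinity_radius=vicinity_radius)
    af = area_fraction(labels, roi_mask, objects=objects)
    glia = {}
    if gfap is not None:
        glia["gfap"] = count_glia_clusters(gfap, roi_mask, glia_min_area_px)
    if iba1 is not None:
        glia["iba1"] = count_glia_clusters(iba1, roi_mask, glia_min_area_px)
    return SectionQuantification(
        area_fraction_pct=af,
        counts=category_counts(objects),
        glia_clusters=glia,
        objects=objects,
    )
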