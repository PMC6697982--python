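"""Microglia morphometry from bright-field DAB sections.

Implements the activation-index workflow used on Iba-1-stained RGB
sections: dynamic FWHM thresholding of the blue-intensity and saturation
channels, cell-body segmentation with small-object and border filtering,
an edge-based process (branch) segmentation, the area:perimeter
"hydraulic radius" activation index, and Iba-1 density within a
region-of-interest polygon.

The hydraulic radius A/P is a shape compactness score: activated
(amoeboid) microglia have large area and small perimeter, so a high
index; ramified (resting) cells with long thin processes score low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from shapely.geometry import Point, Polygon
from skimage import color as skcolor
from skimage import measure as skmeasure
from skimage import morphology as skmorph

__all__ = [
    "RGBSection",
    "ThresholdPair",
    "LabeledRegions",
    "MorphRecord",
    "DensityRecord",
    "DegenerateHistogramError",
    "dynamic_threshold",
    "stain_threshold",
    "segment_cell_bodies",
    "segment_processes",
    "hydraulic_radius",
    "measure_regions",
    "select_cells",
    "iba1_density",
    "activation_index_summary",
]

AREA_MIN_PX = 2000  # published small-object cutoff at 60x acquisition
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


class DegenerateHistogramError(ValueError):
    """Raised when a channel histogram has no spread to fit a curve to."""


@dataclass
class RGBSection:
    """A 2-D RGB section image with physical pixel size (um/px)."""

    pixels: np.ndarray
    pixel_size: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RGBSection requires an H x W x 3 array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class ThresholdPair:
    low: float
    high: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low threshold exceeds high threshold")

    def mask(self, image: np.ndarray) -> np.ndarray:
        return (image >= self.low) & (image <= self.high)


@dataclass
class LabeledRegions:
    """Connected-component labels plus per-region bookkeeping."""

    label_image: np.ndarray
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    areas: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    touches_border: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "LabeledRegions":
        lab, n = ndimage.label(mask)
        # relabel consecutively 1..n (ndimage already does)
        ids = np.arange(1, n + 1)
        areas = ndimage.sum_labels(np.ones_like(lab), lab, ids).astype(int) if n else np.empty(0, int)
        border = np.zeros(n, dtype=bool)
        if n:
            edge_labels = np.unique(np.concatenate([
                lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
            border[edge_labels[edge_labels > 0] - 1] = True
        return cls(label_image=lab, ids=ids, areas=areas, touches_border=border)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.label_image == region_id

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class MorphRecord:
    cell_id: int
    area_px: float
    perimeter_px: float
    hydraulic_radius_px: float
    area_um2: float
    perimeter_um: float
    hydraulic_radius_um: float
    selected: bool = True


@dataclass(frozen=True)
class DensityRecord:
    n_cells: int
    roi_area_mm2: float
    density_per_mm2: float


# ---------------------------------------------------------------------------
# dynamic thresholding
# ---------------------------------------------------------------------------


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_gaussian(centers: np.ndarray, counts: np.ndarray):
    """Least-squares single-Gaussian fit to a histogram; None on failure."""
    if counts.sum() <= 0:
        return None
    peak = int(np.argmax(counts))
    mu0 = float(centers[peak])
    # initialize sigma from the local half-max width around the peak, not the
    # global histogram spread: a narrow spike over a broad histogram otherwise
    # starts the fit far from the optimum and it fails to converge
    half = counts[peak] / 2.0
    lo_i = peak
    while lo_i > 0 and counts[lo_i] > half:
        lo_i -= 1
    hi_i = peak
    while hi_i < len(counts) - 1 and counts[hi_i] > half:
        hi_i += 1
    bin_w = centers[1] - centers[0] if len(centers) > 1 else 1.0
    sd0 = max(float((hi_i - lo_i) * bin_w) / _FWHM_PER_SIGMA, float(bin_w) / 2.0)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, centers, counts,
            p0=[counts[peak], mu0, sd0],
            bounds=([0, centers.min() - 1, 1e-9],
                    [np.inf, centers.max() + 1, np.inf]),
            maxfev=10000)
    except (RuntimeError, ValueError):
        return None
    return popt  # amp, mu, sigma


def _halfmax_band(centers: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Half-max crossings of a smoothed raw histogram (fit fallback)."""
    smooth = ndimage.gaussian_filter1d(counts.astype(float), sigma=2.0)
    peak = np.argmax(smooth)
    half = smooth[peak] / 2.0
    lo = peak
    while lo > 0 and smooth[lo] > half:
        lo -= 1
    hi = peak
    while hi < len(smooth) - 1 and smooth[hi] > half:
        hi += 1
    return float(centers[lo]), float(centers[hi])


def _histogram(image: np.ndarray, bins: int = 256):
    vals = np.asarray(image, dtype=float).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant image: histogram has no spread")
    counts, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts, lo, hi


def dynamic_threshold(channel_image: np.ndarray, bins: int = 256,
                      channel: str = "") -> ThresholdPair:
    """FWHM band of a unimodal curve fit to the channel histogram.

    Fits a single Gaussian to a 256-bin histogram by nonlinear least
    squares and returns ``[peak - FWHM/2, peak + FWHM/2]`` as the accepted
    band, clipped to the observed intensity range.  Falls back to the
    half-max crossings of the smoothed raw histogram when the fit fails.

    Raises :class:`DegenerateHistogramError` for a constant image.
    """
    centers, counts, lo, hi = _histogram(channel_image, bins)
    popt = _fit_gaussian(centers, counts)
    if popt is not None:
        _, mu, sigma = popt
        half = _FWHM_PER_SIGMA * sigma / 2.0
        band = (mu - half, mu + half)
    else:
        band = _halfmax_band(centers, counts)
    return ThresholdPair(low=max(band[0], lo), high=min(band[1], hi),
                         channel=channel)


def stain_threshold(channel_image: np.ndarray, bins: int = 256,
                    channel: str = "", side: str | None = None
                    ) -> ThresholdPair | None:
    """FWHM band of the stain mode of a channel histogram.

    On DAB sections the dominant histogram mode is the light background;
    a band around it would select background, not cells.  This fits the
    dominant Gaussian first, suppresses its neighbourhood from the
    histogram, then fits Gaussians to the residual mass (the stain) and
    returns the stain mode's FWHM band.  When the residual itself is
    multimodal (e.g. densely stained cell bodies plus fainter processes),
    ``side`` picks the most-stained mode: ``'low'`` for an intensity
    channel where stain is dark (blue), ``'high'`` where stain is bright
    (saturation).  Returns None when no distinct secondary mode exists
    (a cell-free image).
    """
    centers, counts, lo, hi = _histogram(channel_image, bins)
    dom = _fit_gaussian(centers, counts)
    if dom is None:
        return None
    residual = counts.astype(float).copy()
    _, mu, sigma = dom
    residual[np.abs(centers - mu) <= 1.5 * _FWHM_PER_SIGMA * sigma] = 0.0

    candidates = []
    for _ in range(2):  # up to two residual stain modes
        if residual.sum() < 0.002 * counts.sum():
            break
        fit = _fit_gaussian(centers, residual)
        if fit is None:
            break
        candidates.append(fit)
        _, mu_i, sigma_i = fit
        residual = residual.copy()
        residual[np.abs(centers - mu_i) <= 1.5 * _FWHM_PER_SIGMA * sigma_i] = 0.0
    if not candidates:
        return None
    if side == "low":
        _, mu2, sigma2 = min(candidates, key=lambda f: f[1])
    elif side == "high":
        _, mu2, sigma2 = max(candidates, key=lambda f: f[1])
    else:
        _, mu2, sigma2 = candidates[0]
    half = _FWHM_PER_SIGMA * sigma2 / 2.0
    return ThresholdPair(low=max(mu2 - half, lo), high=min(mu2 + half, hi),
                         channel=channel)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _saturation(section: RGBSection) -> np.ndarray:
    return skcolor.rgb2hsv(section.pixels)[..., 1]


def _filter_mask(mask: np.ndarray, area_min_px: int) -> np.ndarray:
    """Published region filters: drop under-area_min_px objects and border-touchers."""
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask.copy()
    ids = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(lab), lab, ids)
    drop = areas < area_min_px  # regions *under* the cutoff are removed
    edge = np.unique(np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
    drop[edge[edge > 0] - 1] = True
    keep = ids[~drop]
    return np.isin(lab, keep)


def segment_cell_bodies(section: RGBSection, area_min_px: int = AREA_MIN_PX,
                        erosion_radius: int = 2) -> LabeledRegions:
    """Segment cell bodies by dynamic thresholding of blue and saturation.

    A pixel is selected if it falls in the stain band of *either* the blue
    intensity channel or the saturation channel.  Connected regions under
    ``area_min_px`` pixels or touching the image border are removed, and
    the survivors are eroded (disc radius ``erosion_radius``) to conform
    to cell bodies.  An empty result is valid (no cells found).
    """
    blue = section.pixels[..., 2].astype(float)
    sat = _saturation(section)
    mask = np.zeros(section.pixels.shape[:2], dtype=bool)
    for image, name, side in ((blue, "blue", "low"),
                              (sat, "saturation", "high")):
        try:
            band = stain_threshold(image, channel=name, side=side)
        except DegenerateHistogramError:
            band = None
        if band is not None:
            mask |= band.mask(image)
    # band masks are porous under pixel noise (the FWHM band keeps ~76% of a
    # Gaussian mode); close and fill before the filters so regions are solid.
    # closing runs on an edge-replicated pad so border contact is preserved
    # (zero padding would retreat border-touching regions off the border)
    pad = np.pad(mask, 2, mode="edge")
    pad = ndimage.binary_closing(pad, skmorph.disk(2))
    mask = pad[2:-2, 2:-2]
    mask = ndimage.binary_fill_holes(mask)
    mask = _filter_mask(mask, area_min_px)
    if erosion_radius > 0:
        mask = ndimage.binary_erosion(mask, skmorph.disk(erosion_radius))
    return LabeledRegions.from_mask(mask)


LAPLACIAN_KERNEL = np.array([[-1.0, -1.0, -1.0],
                             [-1.0, 8.0, -1.0],
                             [-1.0, -1.0, -1.0]])


def segment_processes(section: RGBSection, bodies: LabeledRegions,
                      blur_sigma: float = 3.0,
                      kernel: np.ndarray = LAPLACIAN_KERNEL,
                      response_frac: float = 0.8,
                      area_min_px: int = AREA_MIN_PX,
                      dilation_radius: int = 2) -> np.ndarray:
    """Add thin cellular processes to the cell-body segmentation.

    Saturation channel only: Gaussian blur, square, convolve with an
    edge-detection kernel, keep responses within ``response_frac`` of the
    maximum, apply the same small-object/border filters, outline the
    surviving regions, subtract body pixels, dilate the remainder and
    union it with the body mask.  Returns the combined binary mask.
    """
    sat = _saturation(section)
    resp = ndimage.gaussian_filter(sat, blur_sigma) ** 2
    resp = ndimage.convolve(resp, kernel, mode="nearest")
    body_mask = bodies.label_image > 0
    if resp.max() <= 0:
        return body_mask
    mask = resp >= response_frac * resp.max()
    mask = _filter_mask(mask, area_min_px)
    if not mask.any():
        return body_mask
    outline = mask & ~ndimage.binary_erosion(mask, skmorph.disk(1))
    processes = outline & ~body_mask
    if dilation_radius > 0:
        processes = ndimage.binary_dilation(processes, skmorph.disk(dilation_radius))
    return body_mask | processes


# ---------------------------------------------------------------------------
# hydraulic radius
# ---------------------------------------------------------------------------


def _contour_perimeter(mask: np.ndarray) -> float:
    """Total arc length of the marching-squares iso-contour of the region."""
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in skmeasure.find_contours(padded, 0.5):
        d = np.diff(contour, axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def _perimeter(mask: np.ndarray, estimator: str) -> float:
    if estimator == "contour":
        return _contour_perimeter(mask)
    if estimator == "crofton":
        return float(skmeasure.perimeter_crofton(mask, directions=4))
    if estimator == "pixel":
        return float(skmeasure.perimeter(mask, neighborhood=4))
    raise ValueError(f"unknown perimeter estimator: {estimator!r}")


def hydraulic_radius(region_mask: np.ndarray, pixel_size: float = 1.0,
                     cell_id: int = 0, estimator: str = "contour",
                     selected: bool = True) -> MorphRecord:
    """Area:perimeter ratio of one segmented region.

    Area is the pixel count; the default perimeter estimator is the
    marching-squares contour length, which stays within a few percent of
    the continuous perimeter for compact discs, axis-aligned rectangles
    and 1-px-wide strips alike.  The Crofton 4-direction approximation
    (``'crofton'``; near-exact on discs, ~6% low on axis-aligned squares)
    and a weighted boundary-pixel count (``'pixel'``) are available as
    flags.  Raises on an empty region.
    """
    area = int(np.count_nonzero(region_mask))
    if area == 0:
        raise ValueError("empty region has no hydraulic radius")
    perim = _perimeter(np.asarray(region_mask, dtype=bool), estimator)
    hr = area / perim
    return MorphRecord(
        cell_id=cell_id,
        area_px=area, perimeter_px=perim, hydraulic_radius_px=hr,
        area_um2=area * pixel_size ** 2,
        perimeter_um=perim * pixel_size,
        hydraulic_radius_um=hr * pixel_size,
        selected=selected,
    )


def measure_regions(regions: LabeledRegions, pixel_size: float = 1.0,
                    estimator: str = "contour",
                    selected_ids=None) -> pd.DataFrame:
    """MorphRecords for every labeled region, as a tidy DataFrame."""
    rows = []
    sel = set(regions.ids if selected_ids is None else selected_ids)
    for rid in regions.ids:
        mask = regions.region_mask(rid)
        rec = hydraulic_radius(mask, pixel_size,
                               cell_id=int(rid), estimator=estimator,
                               selected=rid in sel)
        cy, cx = ndimage.center_of_mass(mask)
        rows.append(dict(**rec.__dict__, y=cy, x=cx))
    return pd.DataFrame(rows, columns=["cell_id", "area_px", "perimeter_px",
                                       "hydraulic_radius_px", "area_um2",
                                       "perimeter_um", "hydraulic_radius_um",
                                       "selected", "y", "x"])


def measure_section_cells(section: RGBSection,
                          body_area_min_px: int = AREA_MIN_PX,
                          process_area_min_px: int | None = None,
                          min_cell_px: int = 50,
                          estimator: str = "contour") -> pd.DataFrame:
    """Full morphometry pass: bodies + processes, one record per cell.

    Segments cell bodies, adds processes, labels the combined mask and
    measures every connected cell above ``min_cell_px``.  The two area
    cutoffs scale with acquisition magnification; the process cutoff
    defaults to the body cutoff.
    """
    bodies = segment_cell_bodies(section, area_min_px=body_area_min_px)
    full = segment_processes(
        section, bodies,
        area_min_px=body_area_min_px if process_area_min_px is None
        else process_area_min_px)
    combined = LabeledRegions.from_mask(full)
    out = measure_regions(combined, section.pixel_size, estimator=estimator)
    return out[out["area_px"] >= min_cell_px].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cell selection
# ---------------------------------------------------------------------------


def select_cells(regions: LabeledRegions, mode: str = "auto",
                 choices: dict[int, bool] | None = None,
                 area_bounds: tuple[int, int] = (AREA_MIN_PX, 10 ** 7),
                 min_solidity: float = 0.0) -> np.ndarray:
    """Flag regions to quantify, mimicking manual cell curation.

    ``mode='auto'`` applies documented proxies for the manual criteria
    (in focus, completely segmented, fully contained): no border contact
    and area/solidity bounds.  ``mode='replay'`` applies a recorded
    ``choices`` mapping (region id -> bool), so a curation session is
    reproducible.  Returns the selected region ids.
    """
    if mode == "replay":
        if choices is None:
            raise ValueError("replay mode requires a choices mapping")
        return np.array([rid for rid in regions.ids if choices.get(int(rid), False)])
    if mode != "auto":
        raise ValueError(f"unknown selection mode: {mode!r}")
    selected = []
    props = {p.label: p for p in skmeasure.regionprops(regions.label_image)}
    for i, rid in enumerate(regions.ids):
        if regions.touches_border[i]:
            continue
        area = regions.areas[i]
        if not (area_bounds[0] <= area <= area_bounds[1]):
            continue
        if min_solidity > 0 and props[rid].solidity < min_solidity:
            continue
        selected.append(rid)
    return np.array(selected, dtype=int)


# ---------------------------------------------------------------------------
# density and group summaries
# ---------------------------------------------------------------------------


def iba1_density(centroids: np.ndarray, roi: Polygon | list,
                 pixel_size: float) -> DensityRecord:
    """Cell density (cells/mm^2) inside an ROI polygon.

    ``centroids`` is an (n, 2) array of (y, x) pixel coordinates (e.g.
    segmented-cell centroids); ``roi`` a shapely Polygon or a vertex list
    in pixel coordinates (vertices inclusive).  Density = count / area.
    """
    poly = roi if isinstance(roi, Polygon) else Polygon([(x, y) for y, x in roi])
    if poly.area == 0:
        raise ValueError("ROI polygon has zero area")
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float)) \
        if np.size(centroids) else np.empty((0, 2))
    n = sum(1 for y, x in centroids
            if poly.covers(Point(x, y)))  # covers: boundary-inclusive
    area_mm2 = poly.area * (pixel_size ** 2) / 1e6
    return DensityRecord(n_cells=n, roi_area_mm2=area_mm2,
                         density_per_mm2=n / area_mm2)


def activation_index_summary(records: pd.DataFrame,
                             index_col: str = "hydraulic_radius_um",
                             animal_col: str = "animal_id",
                             group_col: str = "group") -> pd.DataFrame:
    """Group mean +/- SEM of the activation index, per-animal first.

    Cell-level records are averaged within each animal, then summarized
    per group (mean and SEM over animals).  A single-animal group reports
    SEM as missing (NaN), not zero.  Raises on an empty group structure.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    per_animal = (records.groupby([group_col, animal_col])[index_col]
                  .mean().rename("animal_mean").reset_index())

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    out = (per_animal.groupby(group_col)["animal_mean"]
           .agg(mean="mean", sem=_sem, n_animals="count").reset_index())
    return out
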