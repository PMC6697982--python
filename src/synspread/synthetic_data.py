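"""Synthetic ground-truth generators for every pipeline stage.

Three simulators produce the three kinds of raw data the quantification
pipeline consumes, each with a complete per-object truth record so that
segmentation, classification and differential-expression stages can be
benchmarked without any real acquisition:

* :func:`make_confocal_stack` — a 4-channel 12-bit confocal z-stack
  (DAPI / green / red / syn) containing fluorescent somata, a subset of
  which carry intracellular puncta in the syn channel.
* :func:`make_section_image` — an RGB bright-field image of DAB-stained
  (brown-on-light) cells, mixing compact "amoeboid" blobs and branched
  "ramified" cells, with true area/perimeter measured on the noise-free
  binary render of each cell.
* :func:`make_count_matrix` — gene-level negative-binomial counts for a
  three-group (PBS / LPS / IL-4) bulk RNA-seq design with planted log2
  fold changes between the LPS and IL-4 groups.

Every generator is a pure function of its config (seed included): the
same config yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw
from skimage import measure as skmeasure

__all__ = [
    "StackSimConfig",
    "SectionSimConfig",
    "CountSimConfig",
    "StackTruth",
    "SectionTruth",
    "CountTruth",
    "make_confocal_stack",
    "make_section_image",
    "make_count_matrix",
    "render_amoeboid",
    "render_ramified",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StackSimConfig:
    """Parameters for the confocal z-stack simulator.

    Defaults mirror the acquisition protocol being emulated: 1024 x 1024
    frames, 16 um deep stacks at 0.2 um z-increments (80 slices), 12-bit
    channels.  ``pixel_size`` defaults to 0.5 um/px so that the expected
    soma diameter (~15 um) is ~30 px, matching the default averaging-kernel
    size used downstream.
    """

    seed: int = 0
    width: int = 1024
    height: int = 1024
    n_z: int = 80
    z_step: float = 0.2
    pixel_size: float = 0.5
    n_cells: int = 10
    marker_mix: float = 0.5          # fraction of cells that are TH (red); rest Iba-1 (green)
    frac_positive: float = 0.5       # fraction of cells planted with syn puncta
    puncta_per_cell: int = 3
    punctum_radius: int = 2          # px
    soma_radius: int = 15            # px (in-plane); ~15 um diameter at defaults
    nucleus_radius: int = 6          # px, DAPI
    soma_amplitude: float = 1500.0   # marker-channel soma intensity (12-bit scale)
    punctum_amplitude: float = 2500.0
    background: float = 100.0
    psf_sigma: float = 2.0           # px, in-plane Gaussian PSF sigma
    poisson_scale: float = 1.0       # 0 disables shot noise
    gaussian_sd: float = 30.0        # additive read noise, 0 disables
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.n_z <= 0:
            raise ValueError("stack dimensions must be positive")
        if not 0.0 <= self.frac_positive <= 1.0:
            raise ValueError("frac_positive must lie in [0, 1]")
        if not 0.0 <= self.marker_mix <= 1.0:
            raise ValueError("marker_mix must lie in [0, 1]")
        if self.n_cells == 0 and self.frac_positive > 0:
            raise ValueError("frac_positive > 0 requires at least one cell")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size and z_step must be positive")


@dataclass(frozen=True)
class SectionSimConfig:
    """Parameters for the DAB-stained bright-field section simulator."""

    seed: int = 0
    width: int = 768
    height: int = 768
    n_ramified: int = 10
    n_amoeboid: int = 10
    soma_radius_range: tuple[int, int] = (28, 40)       # amoeboid body radius, px
    ramified_soma_radius_range: tuple[int, int] = (12, 18)
    branch_count_range: tuple[int, int] = (4, 7)
    branch_length_range: tuple[int, int] = (40, 90)     # px
    branch_width: int = 5                               # px
    stain_color: tuple[int, int, int] = (120, 80, 40)   # DAB brown
    background_color: tuple[int, int, int] = (235, 230, 225)
    branch_stain_frac: float = 0.6  # thin processes take up less chromogen
    noise_sd: float = 4.0
    pixel_size: float = 0.25                            # um/px (60x oil acquisition)
    overlap_allowed: bool = False
    margin: int = 8                                     # keep cells off the border

    def __post_init__(self) -> None:
        if self.branch_width < 1:
            raise ValueError("branch_width must be at least 1 px")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")


@dataclass(frozen=True)
class CountSimConfig:
    """Parameters for the negative-binomial bulk RNA-seq count simulator.

    Group sizes default to the study design of 4 PBS, 5 LPS and 8 IL-4
    samples.  DE genes carry a ``de_log2fc`` shift between the LPS and
    IL-4 group means (up in LPS with probability ``de_up_fraction``).
    """

    seed: int = 0
    n_genes: int = 2000
    group_sizes: tuple[int, int, int] = (4, 5, 8)       # (PBS, LPS, IL4)
    baseline_log2cpm_mean: float = 4.0
    baseline_log2cpm_sd: float = 2.0
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (8e6, 12e6)
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    de_up_fraction: float = 0.7                          # fraction of DE genes up in LPS

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if any(n < 0 for n in self.group_sizes):
            raise ValueError("group sizes must be non-negative")


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class StackTruth:
    """Per-cell ground truth for a simulated confocal stack.

    ``cells`` has one row per simulated cell: cell_id, centroid (z, y, x),
    marker ("TH" or "Iba1"), is_positive, n_puncta.  ``punctum_voxels``
    maps cell_id -> (k, 3) integer array of planted punctum-center voxels.
    """

    cells: pd.DataFrame
    punctum_voxels: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class SectionTruth:
    """Per-cell ground truth for a simulated DAB section.

    One row per cell: cell_id, shape_class ("amoeboid"/"ramified"),
    centroid, true_area (px), true_perimeter (px, Crofton 4-direction on
    the noise-free binary render) and true_hydraulic_radius.
    """

    cells: pd.DataFrame
    masks: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class CountTruth:
    """Per-gene ground truth: gene_id, is_de, true_log2fc (LPS vs IL-4)."""

    genes: pd.DataFrame


# ---------------------------------------------------------------------------
# confocal stack simulator
# ---------------------------------------------------------------------------


def _place_centers(rng: np.random.Generator, n: int, shape: tuple[int, int],
                   radius: int, margin: int, min_sep: float,
                   max_tries: int = 20000) -> np.ndarray:
    """Rejection-sample n 2-D centers at least min_sep apart, away from borders."""
    h, w = shape
    lo_y, hi_y = radius + margin, h - radius - margin
    lo_x, hi_x = radius + margin, w - radius - margin
    if hi_y <= lo_y or hi_x <= lo_x:
        raise ValueError("image too small for the requested cell radius")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place all cells without overlap; "
                             "reduce n_cells or cell size")
        y = rng.uniform(lo_y, hi_y)
        x = rng.uniform(lo_x, hi_x)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep ** 2 for cy, cx in centers):
            centers.append((y, x))
    return np.asarray(centers)


def _add_ball(vol: np.ndarray, center: tuple[float, float, float],
              r_xy: float, r_z: float, amplitude: float) -> np.ndarray:
    """Paint an axis-aligned ellipsoid into vol (z, y, x); returns voxel coords."""
    cz, cy, cx = center
    z0, z1 = int(max(0, np.floor(cz - r_z))), int(min(vol.shape[0], np.ceil(cz + r_z) + 1))
    y0, y1 = int(max(0, np.floor(cy - r_xy))), int(min(vol.shape[1], np.ceil(cy + r_xy) + 1))
    x0, x1 = int(max(0, np.floor(cx - r_xy))), int(min(vol.shape[2], np.ceil(cx + r_xy) + 1))
    if z1 <= z0 or y1 <= y0 or x1 <= x0:  # entirely outside the volume
        return np.empty((0, 3), dtype=int)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    inside = (((zz - cz) / max(r_z, 1e-9)) ** 2
              + ((yy - cy) / r_xy) ** 2
              + ((xx - cx) / r_xy) ** 2) <= 1.0
    vol[z0:z1, y0:y1, x0:x1][inside] = np.maximum(
        vol[z0:z1, y0:y1, x0:x1][inside], amplitude)
    coords = np.stack([zz[inside], yy[inside], xx[inside]], axis=1)
    return coords


def make_confocal_stack(cfg: StackSimConfig):
    """Simulate a 4-channel confocal z-stack with per-cell ground truth.

    Returns ``(stack, truth)`` where ``stack`` is a
    :class:`synspread.transfer_quant.ChannelStack` and ``truth`` a
    :class:`StackTruth`.  The number of syn-positive cells is exactly
    ``round(n_cells * frac_positive)``, assigned without replacement.
    Rendering order: paint ideal intensities, Gaussian PSF blur (z sigma
    scaled by z_step/pixel_size), scaled Poisson shot noise, additive
    Gaussian read noise, clip and quantize to ``bit_depth`` bits.
    """
    from .transfer_quant import ChannelStack  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_z, cfg.height, cfg.width)
    channels = {name: np.zeros(shape, dtype=np.float64)
                for name in ("dapi", "green", "red", "syn")}

    # z-extent of a soma in slices (soma is round in physical space)
    r_z = cfg.soma_radius * cfg.pixel_size / cfg.z_step
    n_pos = int(round(cfg.n_cells * cfg.frac_positive))

    records = []
    punctum_voxels: dict[int, np.ndarray] = {}
    if cfg.n_cells > 0:
        centers = _place_centers(rng, cfg.n_cells, (cfg.height, cfg.width),
                                 cfg.soma_radius, margin=2,
                                 min_sep=2.4 * cfg.soma_radius)
        n_th = int(round(cfg.n_cells * cfg.marker_mix))
        markers = np.array(["TH"] * n_th + ["Iba1"] * (cfg.n_cells - n_th))
        rng.shuffle(markers)
        positive_ids = rng.choice(cfg.n_cells, size=n_pos, replace=False)
        is_positive = np.zeros(cfg.n_cells, dtype=bool)
        is_positive[positive_ids] = True

        z_lo = max(r_z + 1, 0.25 * cfg.n_z)
        z_hi = min(cfg.n_z - r_z - 1, 0.75 * cfg.n_z)
        if z_hi < z_lo:  # shallow stacks: center everything mid-stack
            z_lo = z_hi = cfg.n_z / 2.0
        for cid in range(cfg.n_cells):
            cy, cx = centers[cid]
            cz = rng.uniform(z_lo, z_hi)
            marker_channel = "red" if markers[cid] == "TH" else "green"
            _add_ball(channels[marker_channel], (cz, cy, cx),
                      cfg.soma_radius, r_z, cfg.soma_amplitude)
            _add_ball(channels["dapi"], (cz, cy, cx),
                      cfg.nucleus_radius,
                      cfg.nucleus_radius * cfg.pixel_size / cfg.z_step,
                      cfg.soma_amplitude)
            if is_positive[cid]:
                pts = []
                pr_z = max(cfg.punctum_radius * cfg.pixel_size / cfg.z_step, 0.5)
                for _ in range(cfg.puncta_per_cell):
                    # puncta strictly inside the soma volume
                    rr = rng.uniform(0, 0.6 * cfg.soma_radius)
                    th = rng.uniform(0, 2 * np.pi)
                    # inside the soma and inside the imaged stack depth
                    pz = float(np.clip(cz + rng.uniform(-0.4, 0.4) * r_z,
                                       1.0, cfg.n_z - 2.0))
                    py, px = cy + rr * np.sin(th), cx + rr * np.cos(th)
                    _add_ball(channels["syn"], (pz, py, px),
                              cfg.punctum_radius, pr_z, cfg.punctum_amplitude)
                    pts.append((int(round(pz)), int(round(py)), int(round(px))))
                punctum_voxels[cid] = np.asarray(pts, dtype=int)
            records.append(dict(cell_id=cid, z=cz, y=cy, x=cx,
                                marker=markers[cid],
                                is_positive=bool(is_positive[cid]),
                                n_puncta=cfg.puncta_per_cell if is_positive[cid] else 0))

    max_val = 2 ** cfg.bit_depth - 1
    sigma_z = (cfg.psf_sigma * cfg.pixel_size / cfg.z_step) if cfg.psf_sigma > 0 else 0.0
    voxels = np.empty((4, *shape), dtype=np.uint16)
    order = ["dapi", "green", "red", "syn"]
    for i, name in enumerate(order):
        img = channels[name] + cfg.background
        if cfg.psf_sigma > 0:
            img = ndimage.gaussian_filter(img, sigma=(sigma_z, cfg.psf_sigma, cfg.psf_sigma))
        if cfg.poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * cfg.poisson_scale) / cfg.poisson_scale
        if cfg.gaussian_sd > 0:
            img = img + rng.normal(0.0, cfg.gaussian_sd, size=img.shape)
        voxels[i] = np.clip(np.round(img), 0, max_val).astype(np.uint16)

    truth = StackTruth(
        cells=pd.DataFrame(records, columns=["cell_id", "z", "y", "x", "marker",
                                             "is_positive", "n_puncta"]),
        punctum_voxels=punctum_voxels,
    )
    stack = ChannelStack(
        voxels=voxels,
        channel_map={name: i for i, name in enumerate(order)},
        bit_depth=cfg.bit_depth,
        pixel_size=cfg.pixel_size,
        z_step=cfg.z_step,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# DAB section simulator
# ---------------------------------------------------------------------------


def render_amoeboid(radius: int, shape: tuple[int, int],
                    center: tuple[int, int]) -> np.ndarray:
    """Binary render of a compact (activated-morphology) cell: a filled disc."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.disk(center, radius, shape=shape)
    mask[rr, cc] = True
    return mask


def render_ramified(soma_radius: int, branch_lengths: np.ndarray,
                    branch_angles: np.ndarray, branch_width: int,
                    shape: tuple[int, int], center: tuple[int, int]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Binary render of a ramified cell: small soma plus thin radial branches.

    Returns ``(soma_mask, branch_mask)`` separately so the two compartments
    can be stained with different intensities.
    """
    soma = np.zeros(shape, dtype=bool)
    branches = np.zeros(shape, dtype=bool)
    cy, cx = center
    rr, cc = skdraw.disk(center, soma_radius, shape=shape)
    soma[rr, cc] = True
    for length, angle in zip(branch_lengths, branch_angles):
        ey = cy + length * np.sin(angle)
        ex = cx + length * np.cos(angle)
        ey = float(np.clip(ey, 0, shape[0] - 1))
        ex = float(np.clip(ex, 0, shape[1] - 1))
        rr, cc = skdraw.line(int(round(cy)), int(round(cx)),
                             int(round(ey)), int(round(ex)))
        line = np.zeros(shape, dtype=bool)
        line[rr, cc] = True
        if branch_width > 1:
            line = ndimage.binary_dilation(
                line, structure=ndimage.generate_binary_structure(2, 2),
                iterations=(branch_width - 1) // 2 + (branch_width - 1) % 2)
        branches |= line
    branches &= ~soma
    return soma, branches


def _cell_truth_row(cid: int, mask: np.ndarray, shape_class: str) -> dict:
    from .morphometry import _contour_perimeter

    area = int(mask.sum())
    perim = _contour_perimeter(mask)
    cy, cx = ndimage.center_of_mass(mask)
    return dict(cell_id=cid, shape_class=shape_class, y=cy, x=cx,
                true_area=area, true_perimeter=perim,
                true_hydraulic_radius=area / perim if perim > 0 else np.nan)


def make_section_image(cfg: SectionSimConfig):
    """Simulate an RGB DAB-stained section with per-cell geometric truth.

    Ramified cells (thin branched silhouettes) and amoeboid cells (compact
    discs) are rendered brown on a light background; truth area and
    perimeter are measured on each cell's noise-free binary render before
    noise is added.  Returns ``(section, truth)`` where ``section`` is a
    :class:`synspread.morphometry.RGBSection`.
    """
    from .morphometry import RGBSection

    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    n_total = cfg.n_ramified + cfg.n_amoeboid

    # effective footprint radius used for placement spacing
    reach = max(cfg.soma_radius_range[1],
                cfg.ramified_soma_radius_range[1] + cfg.branch_length_range[1])
    min_sep = 0.0 if cfg.overlap_allowed else 2.0 * reach * 0.75
    centers = _place_centers(rng, n_total, shape, radius=reach // 2,
                             margin=cfg.margin, min_sep=min_sep) if n_total else np.empty((0, 2))

    classes = ["ramified"] * cfg.n_ramified + ["amoeboid"] * cfg.n_amoeboid
    records, masks = [], {}
    body_union = np.zeros(shape, dtype=bool)
    branch_union = np.zeros(shape, dtype=bool)
    for cid, shape_class in enumerate(classes):
        center = (int(round(centers[cid, 0])), int(round(centers[cid, 1])))
        if shape_class == "amoeboid":
            radius = int(rng.integers(cfg.soma_radius_range[0],
                                      cfg.soma_radius_range[1] + 1))
            mask = render_amoeboid(radius, shape, center)
            body_union |= mask
        else:
            soma_r = int(rng.integers(cfg.ramified_soma_radius_range[0],
                                      cfg.ramified_soma_radius_range[1] + 1))
            n_branch = int(rng.integers(cfg.branch_count_range[0],
                                        cfg.branch_count_range[1] + 1))
            lengths = rng.integers(cfg.branch_length_range[0],
                                   cfg.branch_length_range[1] + 1, size=n_branch)
            angles = (rng.uniform(0, 2 * np.pi / n_branch)
                      + np.arange(n_branch) * 2 * np.pi / n_branch)
            soma, branches = render_ramified(soma_r, lengths, angles,
                                             cfg.branch_width, shape, center)
            mask = soma | branches
            body_union |= soma
            branch_union |= branches
        records.append(_cell_truth_row(cid, mask, shape_class))
        masks[cid] = mask

    img = np.empty((*shape, 3), dtype=np.float64)
    bg = np.asarray(cfg.background_color, dtype=np.float64)
    stain = np.asarray(cfg.stain_color, dtype=np.float64)
    img[:] = bg
    img[branch_union] = (cfg.branch_stain_frac * stain
                         + (1.0 - cfg.branch_stain_frac) * bg)
    img[body_union] = stain
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = SectionTruth(
        cells=pd.DataFrame(records, columns=["cell_id", "shape_class", "y", "x",
                                             "true_area", "true_perimeter",
                                             "true_hydraulic_radius"]),
        masks=masks,
    )
    return RGBSection(pixels=img, pixel_size=cfg.pixel_size,
                      provenance=f"synthetic seed={cfg.seed}"), truth


# ---------------------------------------------------------------------------
# RNA-seq count simulator
# ---------------------------------------------------------------------------

GROUPS = ("PBS", "LPS", "IL4")


def make_count_matrix(cfg: CountSimConfig):
    """Simulate a genes x samples negative-binomial count matrix.

    Baseline per-gene abundances are drawn log-normally on the log2CPM
    scale; DE genes (a ``de_fraction`` subset) have their LPS and IL-4
    group means separated by ``de_log2fc`` (split symmetrically about the
    baseline; PBS stays at baseline).  Counts are gamma-Poisson with the
    given dispersion; ``dispersion=0`` reduces to Poisson.

    Returns ``(counts, truth)`` where ``counts`` is a
    :class:`synspread.transcriptomics.CountMatrix`.
    """
    from .transcriptomics import CountMatrix

    rng = np.random.default_rng(cfg.seed)
    n_pbs, n_lps, n_il4 = cfg.group_sizes
    n_samples = n_pbs + n_lps + n_il4
    groups = np.array(["PBS"] * n_pbs + ["LPS"] * n_lps + ["IL4"] * n_il4)

    base_log2cpm = rng.normal(cfg.baseline_log2cpm_mean,
                              cfg.baseline_log2cpm_sd, size=cfg.n_genes)
    n_de = int(round(cfg.n_genes * cfg.de_fraction))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    is_de[de_idx] = True
    sign = np.where(rng.random(cfg.n_genes) < cfg.de_up_fraction, 1.0, -1.0)
    true_lfc = np.where(is_de, sign * cfg.de_log2fc, 0.0)

    # baseline proportions are normalized once (before the DE shift), so the
    # planted LPS/IL-4 group-mean ratio of a DE gene is exactly 2^lfc; the
    # shift itself then perturbs realized library sums, giving the realistic
    # compositional asymmetry TMM exists to correct
    lib_sizes = rng.uniform(*cfg.library_size_range, size=n_samples)
    base_rel = 2.0 ** base_log2cpm
    base_rel = base_rel / base_rel.sum()
    shift = np.ones((cfg.n_genes, n_samples))
    shift[:, groups == "LPS"] = (2.0 ** (true_lfc / 2.0))[:, None]
    shift[:, groups == "IL4"] = (2.0 ** (-true_lfc / 2.0))[:, None]
    mu = base_rel[:, None] * lib_sizes[None, :] * shift

    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        lam = rng.gamma(shape, mu * cfg.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    gene_ids = np.array([f"gene{i:05d}" for i in range(cfg.n_genes)])
    sample_ids = np.array([f"{g}_{i}" for i, g in enumerate(groups)])
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        groups=pd.Series(groups, index=sample_ids),
    )
    truth = CountTruth(genes=pd.DataFrame(
        dict(gene_id=gene_ids, is_de=is_de, true_log2fc=true_lfc)))
    return cm, truth
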