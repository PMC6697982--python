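"""Optical-fractionator stereology: total-count estimate and error coefficient.

The optical fractionator estimates the total number of cells in a region
from systematic uniform sampling at three levels: every ``interval``-th
section (section sampling fraction ssf = 1/interval), counting frames on
a regular grid within each sampled section (area sampling fraction
asf = frame area / grid area), and an optical dissector of height h
within the mounted section thickness t (thickness sampling fraction
tsf = h/t).  The estimate is N = sum(Q) / (ssf * asf * tsf), with Q the
raw dissector counts.  The Gundersen-Jensen coefficient of error
combines Poisson counting noise with the systematic-sampling variance
built from lag-0/1/2 products of the per-section counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StereologyDesign",
    "GRAFT_DESIGN",
    "NIGRAL_DESIGN",
    "fractionator_estimate",
    "gundersen_ce",
    "simulate_point_population",
    "sample_fractionator_counts",
]


@dataclass(frozen=True)
class StereologyDesign:
    """Sampling design: section interval, counting frame, grid, dissector."""

    section_interval: int          # every k-th section: ssf = 1/k
    frame_w: float                 # um
    frame_h: float                 # um
    grid_w: float                  # um
    grid_h: float                  # um
    dissector_height: float        # um
    section_thickness: float       # um (nominal cut thickness)
    guard_zone: float = 2.0        # um

    def __post_init__(self) -> None:
        if self.section_interval < 1:
            raise ValueError("section interval must be >= 1")
        if not 0 < self.asf <= 1:
            raise ValueError("frame must fit inside the grid (0 < asf <= 1)")
        if not 0 < self.tsf <= 1:
            raise ValueError("dissector must fit in the section (0 < tsf <= 1)")
        if 2 * self.guard_zone + self.dissector_height > self.section_thickness:
            raise ValueError("guard zones plus dissector exceed section thickness")

    @property
    def ssf(self) -> float:
        return 1.0 / self.section_interval

    @property
    def asf(self) -> float:
        return (self.frame_w * self.frame_h) / (self.grid_w * self.grid_h)

    @property
    def tsf(self) -> float:
        return self.dissector_height / self.section_thickness


# the two published sampling designs
GRAFT_DESIGN = StereologyDesign(section_interval=6, frame_w=70, frame_h=70,
                                grid_w=150, grid_h=150, dissector_height=12,
                                section_thickness=30, guard_zone=2)
NIGRAL_DESIGN = StereologyDesign(section_interval=8, frame_w=100, frame_h=100,
                                 grid_w=200, grid_h=200, dissector_height=12,
                                 section_thickness=30, guard_zone=2)


def fractionator_estimate(counts, design: StereologyDesign) -> float:
    """Total-count estimate: sum(Q) x (1/ssf) x (1/asf) x (1/tsf)."""
    q = np.asarray(counts, dtype=float)
    if (q < 0).any():
        raise ValueError("dissector counts must be non-negative")
    return float(q.sum() / (design.ssf * design.asf * design.tsf))


def gundersen_ce(counts, m: int = 1) -> float:
    """Gundersen-Jensen coefficient of error of a systematic count series.

    ``m`` selects the smoothness class of the sampled quantity: m=1
    (smooth, the usual choice for cell counts; denominator 240) or m=0
    (denominator 12).  CE = sqrt(noise + var_srs) / sum(Q) with
    noise = sum(Q) and var_srs from the lag-0/1/2 products
    A = sum(q_i^2), B = sum(q_i q_{i+1}), C = sum(q_i q_{i+2}).
    """
    q = np.asarray(counts, dtype=float)
    if len(q) < 3:
        raise ValueError("CE needs at least three sections")
    total = q.sum()
    if total <= 0:
        raise ValueError("total count is zero")
    a = float(np.sum(q * q))
    b = float(np.sum(q[:-1] * q[1:]))
    c = float(np.sum(q[:-2] * q[2:]))
    noise = total
    if m == 1:
        var_srs = (3.0 * (a - noise) - 4.0 * b + c) / 240.0
    elif m == 0:
        var_srs = (3.0 * (a - noise) - 4.0 * b + c) / 12.0
    else:
        raise ValueError("smoothness m must be 0 or 1")
    return float(np.sqrt(noise + max(var_srs, 0.0)) / total)


# ---------------------------------------------------------------------------
# simulation of the full sampling scheme (for unbiasedness checks)
# ---------------------------------------------------------------------------


def simulate_point_population(n_points: int, extent_um: tuple[float, float, float],
                              rng: np.random.Generator) -> np.ndarray:
    """Uniform random cell positions (x, y, z in um) in a box region."""
    lo = np.zeros(3)
    hi = np.asarray(extent_um, dtype=float)
    return rng.uniform(lo, hi, size=(n_points, 3))


def sample_fractionator_counts(points: np.ndarray,
                               extent_um: tuple[float, float, float],
                               design: StereologyDesign,
                               rng: np.random.Generator) -> np.ndarray:
    """Apply the fractionator sampling design to a known point population.

    The region is cut into ``section_thickness``-thick sections along z;
    every ``interval``-th section from a random start is sampled.  Within
    a sampled section, counting frames are laid on a regular grid with a
    random offset, and a point is counted when it falls inside a frame
    and inside the dissector depth (below the random guard start).
    Returns the per-section Q counts for the sampled sections.
    """
    ex, ey, ez = extent_um
    t = design.section_thickness
    n_sections = int(np.floor(ez / t))
    start = int(rng.integers(design.section_interval))
    gx = rng.uniform(0, design.grid_w)
    gy = rng.uniform(0, design.grid_h)
    z_lo_in_section = rng.uniform(0, t - design.dissector_height)

    counts = []
    for s in range(start, n_sections, design.section_interval):
        z0 = s * t
        sel = (points[:, 2] >= z0 + z_lo_in_section) & \
              (points[:, 2] < z0 + z_lo_in_section + design.dissector_height)
        if not sel.any():
            counts.append(0)
            continue
        px = np.mod(points[sel, 0] - gx, design.grid_w)
        py = np.mod(points[sel, 1] - gy, design.grid_h)
        in_frame = (px < design.frame_w) & (py < design.frame_h)
        counts.append(int(in_frame.sum()))
    return np.asarray(counts, dtype=int)
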