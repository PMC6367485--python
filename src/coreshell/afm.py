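"""AFM image analysis: flattening, particle detection, per-particle
height/width measurement, shape correction and log-normal distribution fits.

The analysis chain mirrors standard particle metrology practice: a global
first-order (plane) background is fitted over particle-free pixels and
subtracted, connected regions above a height threshold are labeled, and each
particle is measured by its peak height plus two perpendicular widths taken
at half-maximum height through the peak.  Because soft particles flatten on
the substrate, height underestimates the equivalent-sphere size; the shape
correction factor f = median(d_eq / h) converts height-only data to
equivalent-sphere diameters, with d_eq = (h * w1 * w2)**(1/3) (the
volume-preserving oblate-spheroid convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure as skmeasure

from .topography import AFMTopograph

__all__ = [
    "ParticleMeasurement",
    "LogNormalFit",
    "flatten_first_order",
    "detect_particles",
    "measure_particle",
    "measure_all",
    "equivalent_sphere_diameter",
    "shape_correction_factor",
    "fit_lognormal",
]


@dataclass
class ParticleMeasurement:
    """Height, perpendicular half-max widths and derived equivalent-sphere
    diameter of one detected particle."""

    height_nm: float
    widths_nm: tuple
    d_eq_nm: float | None = None
    aspect: float | None = None
    excluded: bool = False
    reason: str = ""

    def __post_init__(self):
        if not self.excluded:
            if self.height_nm <= 0 or any(w <= 0 for w in self.widths_nm):
                raise ValueError("height and widths must be positive")
            if self.d_eq_nm is None:
                self.d_eq_nm = equivalent_sphere_diameter(self.height_nm, *self.widths_nm)
            if self.aspect is None:
                self.aspect = max(self.widths_nm) / self.height_nm


@dataclass
class LogNormalFit:
    """Maximum-likelihood log-normal fit of a diameter sample."""

    median_nm: float
    sigma_log: float
    mode_nm: float = field(default=None)
    n: int = 0
    goodness: float = float("nan")

    def __post_init__(self):
        if self.mode_nm is None:
            self.mode_nm = self.median_nm * math.exp(-self.sigma_log ** 2)


def flatten_first_order(topo: AFMTopograph, exclusion_mask: np.ndarray | None = None
                        ) -> AFMTopograph:
    """Subtract the best-fit global background plane.

    The plane is fitted by least squares over pixels *not* covered by
    ``exclusion_mask`` (True = exclude, e.g. particle pixels) and subtracted
    from the whole grid, so background pixels end up with zero mean.  The
    operation is a projection: flattening twice equals flattening once.
    """
    z = topo.heights
    if exclusion_mask is None:
        exclusion_mask = np.zeros_like(z, dtype=bool)
    exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
    if exclusion_mask.shape != z.shape:
        raise ValueError("mask shape must match the grid")
    keep = ~exclusion_mask
    if keep.sum() < 3:
        raise ValueError("need at least 3 background pixels to fit a plane")
    ii, jj = np.nonzero(keep)
    A = np.column_stack([np.ones(ii.size), ii.astype(float), jj.astype(float)])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("background pixels are collinear; cannot fit a plane")
    coef, *_ = np.linalg.lstsq(A, z[keep], rcond=None)
    I, J = np.meshgrid(np.arange(z.shape[0]), np.arange(z.shape[1]), indexing="ij")
    plane = coef[0] + coef[1] * I + coef[2] * J
    return AFMTopograph(z - plane, topo.pixel_nm)


def detect_particles(topo: AFMTopograph, min_height_nm: float, min_area_px: int = 4):
    """Label connected regions above a height threshold, filtered by area.

    Returns a list of ``skimage.measure.RegionProperties``; an empty image
    yields an empty list.
    """
    if min_height_nm <= 0:
        raise ValueError("min_height_nm must be > 0")
    binary = topo.heights > min_height_nm
    labels = skmeasure.label(binary, connectivity=2)
    regions = [r for r in skmeasure.regionprops(labels, intensity_image=topo.heights)
               if r.area >= min_area_px]
    return regions


def _halfmax_width(profile: np.ndarray, peak_idx: int, half: float, pixel_nm: float) -> float:
    """Extent of the contiguous run >= half around peak_idx with sub-pixel
    crossings.

    Smooth crossings are located by linear interpolation.  When the profile
    drops past the half level in a single step (the outside sample is far
    below it, as at the equator of an upright particle whose lower half is
    hidden), the edge is taken at the pixel boundary — the unbiased estimate
    for a cliff whose true position is uniform within the pixel.
    """
    n = profile.size
    i = peak_idx
    while i > 0 and profile[i - 1] >= half:
        i -= 1
    if i == 0 or profile[i] == profile[i - 1]:
        left = float(i)
    elif profile[i - 1] < 0.5 * half:  # cliff: sub-half-max side wall hidden
        left = i - 0.5
    else:
        left = i - (profile[i] - half) / (profile[i] - profile[i - 1])
    j = peak_idx
    while j < n - 1 and profile[j + 1] >= half:
        j += 1
    if j == n - 1 or profile[j] == profile[j + 1]:
        right = float(j)
    elif profile[j + 1] < 0.5 * half:
        right = j + 0.5
    else:
        right = j + (profile[j] - half) / (profile[j] - profile[j + 1])
    return (right - left) * pixel_nm


def measure_particle(topo: AFMTopograph, region, max_eccentricity: float = 0.95
                     ) -> ParticleMeasurement:
    """Measure one labeled region on a flattened topograph.

    Height is the peak value (background is zero after flattening); the two
    widths are the half-maximum extents of the row and column profiles
    through the peak.  Regions touching the image border or with
    eccentricity above ``max_eccentricity`` (fused particles) are returned
    flagged ``excluded`` with a reason, never dropped silently.
    """
    z = topo.heights
    minr, minc, maxr, maxc = region.bbox
    if minr == 0 or minc == 0 or maxr == z.shape[0] or maxc == z.shape[1]:
        return ParticleMeasurement(np.nan, (np.nan, np.nan), np.nan, np.nan,
                                   excluded=True, reason="border")
    if region.eccentricity > max_eccentricity:
        return ParticleMeasurement(np.nan, (np.nan, np.nan), np.nan, np.nan,
                                   excluded=True, reason="fused")
    # peak within the region
    sub = z[minr:maxr, minc:maxc] * region.image
    pr, pc = np.unravel_index(np.argmax(sub), sub.shape)
    pr, pc = pr + minr, pc + minc
    h = float(z[pr, pc])
    half = h / 2.0
    w1 = _halfmax_width(z[pr, :], pc, half, topo.pixel_nm)
    w2 = _halfmax_width(z[:, pc], pr, half, topo.pixel_nm)
    return ParticleMeasurement(h, (w1, w2))


def measure_all(topo: AFMTopograph, min_height_nm: float, min_area_px: int = 4,
                max_eccentricity: float = 0.95) -> pd.DataFrame:
    """Detect and measure every particle in a flattened topograph.

    Returns a tidy table with one row per detection, including excluded rows
    with their reasons.
    """
    rows = []
    for region in detect_particles(topo, min_height_nm, min_area_px):
        m = measure_particle(topo, region, max_eccentricity)
        rows.append({"height_nm": m.height_nm,
                     "width1_nm": m.widths_nm[0], "width2_nm": m.widths_nm[1],
                     "d_eq_nm": m.d_eq_nm, "aspect": m.aspect,
                     "excluded": m.excluded, "reason": m.reason})
    return pd.DataFrame(rows, columns=["height_nm", "width1_nm", "width2_nm",
                                       "d_eq_nm", "aspect", "excluded", "reason"])


def equivalent_sphere_diameter(h: float, w1: float, w2: float) -> float:
    """Volume-preserving spheroid equivalent diameter d_eq = (h w1 w2)**(1/3)."""
    if h <= 0 or w1 <= 0 or w2 <= 0:
        raise ValueError("height and widths must be > 0")
    return (h * w1 * w2) ** (1.0 / 3.0)


def shape_correction_factor(measurements) -> tuple[float, float]:
    """Robust shape factor f = median(d_eq / h) with its median absolute
    deviation, over at least 10 particles with width measurements.

    Applied to a height-only population, corrected diameters are ``f * h``.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements
        if "excluded" in df:
            df = df[~df["excluded"].astype(bool)]
        ratios = (df["d_eq_nm"] / df["height_nm"]).to_numpy(float)
    else:
        included = [m for m in measurements if not m.excluded]
        ratios = np.array([m.d_eq_nm / m.height_nm for m in included])
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size < 10:
        raise ValueError("shape factor needs at least 10 particles with widths "
                         f"(got {ratios.size})")
    f = float(np.median(ratios))
    mad = float(np.median(np.abs(ratios - f)))
    return f, mad


def fit_lognormal(diameters, min_n: int = 20) -> LogNormalFit:
    """Maximum-likelihood log-normal fit of a diameter sample.

    Parameterized by median (exp of the mean log-diameter) and sigma_log (SD
    of log-diameters); the mode follows as ``median * exp(-sigma_log**2)``.
    Goodness is the sum of squared residuals between observed and expected
    counts on Doane-binned histograms.
    """
    d = np.asarray(diameters, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} diameters (got {d.size})")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    logs = np.log(d)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))
    median = math.exp(mu)
    counts, edges = np.histogram(d, bins="doane")
    if sigma > 0:
        cdf = stats.lognorm.cdf(edges, sigma, scale=median)
        expected = d.size * np.diff(cdf)
        goodness = float(np.sum((counts - expected) ** 2))
    else:
        goodness = 0.0
    return LogNormalFit(median_nm=median, sigma_log=sigma, n=int(d.size),
                        goodness=goodness)
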