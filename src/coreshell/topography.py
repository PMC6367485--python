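"""Synthetic AFM topographs: spheroidal particles on a tilted, noisy plane.

Particles are rendered as full (optionally oblate) spheroids resting on the
substrate, so the map records the upper surface: a particle of height ``h``
and equatorial width ``w = aspect * h`` contributes

    z(r) = h/2 * (1 + sqrt(1 - (2 r / w)**2)),   r < w/2.

Consequences used downstream: the peak height equals the particle height,
and the extent at half-maximum height equals the equatorial width exactly.
Tip convolution, cantilever dynamics and fluid-imaging artifacts are not
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AFMTopograph", "gen_afm_topograph", "write_topograph", "read_topograph"]


@dataclass
class AFMTopograph:
    """A rectangular height map (nm) with uniform pixel spacing (nm)."""

    heights: np.ndarray
    pixel_nm: float

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")

    @property
    def shape(self):
        return self.heights.shape

    @property
    def field_nm(self):
        ny, nx = self.heights.shape
        return (ny * self.pixel_nm, nx * self.pixel_nm)


def gen_afm_topograph(pop, pixel_nm: float, field_nm: float,
                      tilt_nm_per_px: float = 0.0, noise_sd_nm: float = 0.0,
                      shape_aspect: float = 1.0, seed: int | None = None,
                      margin_nm: float = 5.0, max_tries: int = 2000):
    """Render a particle population into a topograph.

    Particle heights are the population diameters; equatorial widths are
    ``shape_aspect`` times the height.  Centers are placed by rejection
    sampling so particles never overlap or touch the border.  Returns the
    topograph and a ground-truth table (centers, height, widths).

    ``tilt_nm_per_px`` adds a background plane rising along both axes;
    ``noise_sd_nm`` adds i.i.d. Gaussian pixel noise.  A seed is mandatory
    (placement is always stochastic).
    """
    if seed is None:
        raise ValueError("gen_afm_topograph requires an explicit integer seed")
    if pixel_nm <= 0 or field_nm <= 0:
        raise ValueError("pixel_nm and field_nm must be > 0")
    if shape_aspect <= 0:
        raise ValueError("shape_aspect must be > 0")
    rng = np.random.default_rng(int(seed))
    npx = int(round(field_nm / pixel_nm))
    heights = np.asarray(pop.diameters, float)
    widths = shape_aspect * heights

    # quick feasibility check on total footprint
    if np.sum(np.pi * (widths / 2 + margin_nm) ** 2) > 0.7 * field_nm ** 2:
        raise ValueError("field too small for requested particle count")

    centers = np.empty((heights.size, 2))
    placed_r = []
    for i, w in enumerate(widths):
        r = w / 2.0
        lo, hi = r + margin_nm, field_nm - r - margin_nm
        if hi <= lo:
            raise ValueError("field too small for requested particle size")
        for _ in range(max_tries):
            c = rng.uniform(lo, hi, size=2)
            if all(np.hypot(*(c - centers[j])) > r + placed_r[j] + margin_nm
                   for j in range(i)):
                centers[i] = c
                placed_r.append(r)
                break
        else:
            raise ValueError("field too small: could not place particle "
                             f"{i} after {max_tries} tries")

    # pixel-center physical coordinates
    coords = (np.arange(npx) + 0.5) * pixel_nm
    X, Y = np.meshgrid(coords, coords)
    z = np.zeros((npx, npx))
    for (cx, cy), h, w in zip(centers, heights, widths):
        r2 = ((X - cx) ** 2 + (Y - cy) ** 2) / (w / 2.0) ** 2
        inside = r2 < 1.0
        cap = h / 2.0 * (1.0 + np.sqrt(np.clip(1.0 - r2, 0.0, None)))
        z[inside] = np.maximum(z[inside], cap[inside])

    if tilt_nm_per_px:
        jj, ii = np.meshgrid(np.arange(npx), np.arange(npx))
        z = z + tilt_nm_per_px * (ii + jj)
    if noise_sd_nm:
        z = z + rng.normal(0.0, noise_sd_nm, z.shape)

    truth = pd.DataFrame({
        "center_x_nm": centers[:, 0], "center_y_nm": centers[:, 1],
        "height_nm": heights, "width_x_nm": widths, "width_y_nm": widths,
    })
    return AFMTopograph(z, pixel_nm), truth


def write_topograph(topo: AFMTopograph, path) -> None:
    """Write a topograph as a plain-text matrix with a sidecar header."""
    ny, nx = topo.shape
    header = (f"pixel_nm: {topo.pixel_nm}\n"
              f"field_nm: {ny * topo.pixel_nm} {nx * topo.pixel_nm}\n"
              "units: nm")
    np.savetxt(path, topo.heights, header=header)


def read_topograph(path) -> AFMTopograph:
    """Read a topograph written by :func:`write_topograph`."""
    pixel_nm = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "pixel_nm":
                pixel_nm = float(val)
    if pixel_nm is None:
        raise ValueError(f"{path}: missing pixel_nm in sidecar header")
    return AFMTopograph(np.loadtxt(path), pixel_nm)
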