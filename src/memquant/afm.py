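"""AFM height-map quantification for supported membranes.

Operations on 2D height grids (nm): polynomial background leveling, step
heights across template/membrane edges from robust plateau statistics, pore
segmentation with per-pore depth (membrane plateau median minus pore-floor
median), and particle detection with the protein-candidate geometric gates
(5-10 nm height, 10-20 nm diameter at half height) used to count membrane
proteins.  Densities are reported per analyzed membrane area, excluding
template mesas and a 2-pixel border.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import feature, measure, segmentation

__all__ = [
    "Topograph",
    "StepMeasurement",
    "Pore",
    "PoreSet",
    "Particle",
    "ParticleSet",
    "HEIGHT_GATE_NM",
    "DIAMETER_GATE_NM",
    "level",
    "step_height",
    "step_from_profile",
    "detect_pores",
    "detect_particles",
    "attribute_density",
]

HEIGHT_GATE_NM = (5.0, 10.0)
DIAMETER_GATE_NM = (10.0, 20.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Topograph:
    """AFM height grid in nm with its lateral pixel size."""

    heights_nm: np.ndarray
    pixel_size_nm: float
    leveled: bool = False

    def __post_init__(self):
        self.heights_nm = np.asarray(self.heights_nm, dtype=float)
        if self.heights_nm.ndim != 2:
            raise ValueError("height grid must be 2-D")
        if not np.all(np.isfinite(self.heights_nm)):
            raise ValueError("heights must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self):
        return self.heights_nm.shape

    @property
    def area_um2(self) -> float:
        return self.heights_nm.size * (self.pixel_size_nm / 1000.0) ** 2

    def to_tiff(self, path) -> None:
        """32-bit float TIFF (heights in nm) with a JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.heights_nm.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"pixel_size_nm": self.pixel_size_nm,
                                       "units": "nm",
                                       "leveled": self.leveled}))

    @classmethod
    def from_tiff(cls, path) -> "Topograph":
        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".json").read_text())
        return cls(heights_nm=tifffile.imread(path).astype(float),
                   pixel_size_nm=meta["pixel_size_nm"],
                   leveled=meta.get("leveled", False))

    def to_txt(self, path) -> None:
        np.savetxt(path, self.heights_nm, fmt="%.5f")
        Path(str(path) + ".json").write_text(
            json.dumps({"pixel_size_nm": self.pixel_size_nm, "units": "nm"}))

    @classmethod
    def from_txt(cls, path) -> "Topograph":
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(heights_nm=np.loadtxt(path),
                   pixel_size_nm=meta["pixel_size_nm"])


@dataclass
class StepMeasurement:
    """Height step between two plateaus (upper minus lower)."""

    lower_nm: float
    upper_nm: float
    uncertainty_nm: float
    n_lower: int
    n_upper: int

    @property
    def step_height_nm(self) -> float:
        return self.upper_nm - self.lower_nm


@dataclass
class Pore:
    centroid_px: tuple
    diameter_nm: float
    depth_nm: float
    area_nm2: float


@dataclass
class PoreSet:
    pores: list
    analyzed_area_um2: float
    pore_area_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.pore_area_fraction <= 1.0:
            raise ValueError("area fraction must lie in [0, 1]")

    def __len__(self):
        return len(self.pores)

    @property
    def mean_depth_nm(self) -> float:
        if not self.pores:
            return float("nan")
        return float(np.mean([p.depth_nm for p in self.pores]))

    @property
    def mean_diameter_nm(self) -> float:
        if not self.pores:
            return float("nan")
        return float(np.mean([p.diameter_nm for p in self.pores]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "y_px": p.centroid_px[0], "x_px": p.centroid_px[1],
            "diameter_nm": p.diameter_nm, "depth_nm": p.depth_nm,
            "area_nm2": p.area_nm2} for p in self.pores])


@dataclass
class Particle:
    centroid_px: tuple
    height_nm: float
    diameter_nm: float  # equivalent diameter at half height
    gated: bool
    class_label: str  # P1 | P2 | P3 | unclassified


@dataclass
class ParticleSet:
    particles: list
    analyzed_area_um2: float
    height_gate_nm: tuple = HEIGHT_GATE_NM
    diameter_gate_nm: tuple = DIAMETER_GATE_NM

    def __len__(self):
        return len(self.particles)

    @property
    def gated(self) -> list:
        return [p for p in self.particles if p.gated]

    @property
    def density_per_um2(self) -> float:
        """Gated-particle count per analyzed membrane area."""
        return len(self.gated) / self.analyzed_area_um2

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "y_px": p.centroid_px[0], "x_px": p.centroid_px[1],
            "height_nm": round(p.height_nm, 2),
            "diameter_nm": round(p.diameter_nm, 2),
            "gated": p.gated, "class": p.class_label}
            for p in self.particles])


# ---------------------------------------------------------------------------
# leveling
# ---------------------------------------------------------------------------

def _poly_terms(yy, xx, order):
    terms = [np.ones_like(xx)]
    if order >= 1:
        terms += [xx, yy]
    if order >= 2:
        terms += [xx * xx, xx * yy, yy * yy]
    return np.stack([t.ravel() for t in terms], axis=1)


def level(topo: Topograph, order: int = 1,
          exclusion_mask: Optional[np.ndarray] = None) -> Topograph:
    """Subtract a polynomial background plane fit on background pixels only.

    ``exclusion_mask`` marks feature pixels (pores, particles, mesas) to be
    excluded from the plane fit so they do not bias the background.  After
    subtraction the background median is zero.  Idempotent up to numerical
    precision.  Raises if more than 90% of pixels are excluded.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    z = topo.heights_nm
    ny, nx = z.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    yy = yy / max(ny - 1, 1)
    xx = xx / max(nx - 1, 1)
    if exclusion_mask is None:
        bg = np.ones_like(z, dtype=bool)
    else:
        bg = ~np.asarray(exclusion_mask, dtype=bool)
    if bg.mean() < 0.1:
        raise ValueError("more than 90% of pixels excluded from leveling")
    A = _poly_terms(yy, xx, order)
    coef, *_ = np.linalg.lstsq(A[bg.ravel()], z[bg], rcond=None)
    plane = (A @ coef).reshape(z.shape)
    out = z - plane
    out = out - np.median(out[bg])
    return Topograph(heights_nm=out, pixel_size_nm=topo.pixel_size_nm,
                     leveled=True)


# ---------------------------------------------------------------------------
# step heights
# ---------------------------------------------------------------------------

def step_height(topo: Topograph, lower_mask: np.ndarray,
                upper_mask: np.ndarray,
                min_pixels: int = 20) -> StepMeasurement:
    """Step between two plateau regions given as boolean masks.

    Plateau levels are medians (robust to residual features); the
    uncertainty is pooled from the plateau variances.
    """
    lower_mask = np.asarray(lower_mask, dtype=bool)
    upper_mask = np.asarray(upper_mask, dtype=bool)
    n_lo, n_hi = int(lower_mask.sum()), int(upper_mask.sum())
    if n_lo < min_pixels or n_hi < min_pixels:
        raise ValueError(f"both plateaus need >= {min_pixels} pixels")
    lo = topo.heights_nm[lower_mask]
    hi = topo.heights_nm[upper_mask]
    unc = float(np.sqrt(lo.var(ddof=1) / n_lo + hi.var(ddof=1) / n_hi))
    return StepMeasurement(lower_nm=float(np.median(lo)),
                           upper_nm=float(np.median(hi)),
                           uncertainty_nm=unc, n_lower=n_lo, n_upper=n_hi)


def step_from_profile(topo: Topograph, start, end,
                      linewidth: int = 5,
                      min_pixels: int = 20,
                      separation_sigmas: float = 3.0) -> StepMeasurement:
    """Step height along a profile line crossing an edge.

    The profile values are split into two plateaus by thresholding at the
    midpoint between the two level estimates (iterated two-means).  If the
    plateau levels are closer than ``separation_sigmas`` pooled standard
    deviations the plateaus are not separable and an error is raised.
    """
    prof = measure.profile_line(topo.heights_nm, start, end,
                                linewidth=linewidth, mode="reflect")
    v = np.asarray(prof, dtype=float).ravel()
    # two-means split on height values
    thr = 0.5 * (v.min() + v.max())
    for _ in range(50):
        lo, hi = v[v <= thr], v[v > thr]
        if lo.size == 0 or hi.size == 0:
            break
        new = 0.5 * (lo.mean() + hi.mean())
        if np.isclose(new, thr):
            break
        thr = new
    lo, hi = v[v <= thr], v[v > thr]
    if lo.size < min_pixels or hi.size < min_pixels:
        raise ValueError("plateaus not separable along this profile")
    pooled = np.sqrt(0.5 * (lo.var(ddof=1) + hi.var(ddof=1)))
    if (hi.mean() - lo.mean()) < separation_sigmas * pooled:
        raise ValueError("plateaus not separable: step is below the "
                         f"{separation_sigmas} sigma bimodality threshold")
    unc = float(np.sqrt(lo.var(ddof=1) / lo.size + hi.var(ddof=1) / hi.size))
    return StepMeasurement(lower_nm=float(np.median(lo)),
                           upper_nm=float(np.median(hi)),
                           uncertainty_nm=unc,
                           n_lower=int(lo.size), n_upper=int(hi.size))


# ---------------------------------------------------------------------------
# pores
# ---------------------------------------------------------------------------

def _analyzed_mask(shape, template_mask, border_px=2):
    mask = np.ones(shape, dtype=bool)
    mask[:border_px, :] = mask[-border_px:, :] = False
    mask[:, :border_px] = mask[:, -border_px:] = False
    if template_mask is not None:
        mask &= ~np.asarray(template_mask, dtype=bool)
    return mask


def detect_pores(topo: Topograph, min_depth_nm: float = 2.0,
                 min_diameter_nm: float = 30.0,
                 template_mask: Optional[np.ndarray] = None) -> PoreSet:
    """Segment membrane pores (regions below the plateau) and measure them.

    The input must be leveled.  Pixels deeper than half the minimum depth
    below the plateau median are labeled into connected components; each
    component is kept as a pore if its equivalent diameter exceeds
    ``min_diameter_nm`` and its floor depth exceeds ``min_depth_nm``.  Pore
    depth is plateau median minus the pore-floor median (the floor is the
    rim-eroded core of the component, falling back to its deepest quartile).
    """
    if not topo.leveled:
        warnings.warn("detect_pores expects a leveled topograph")
    analyzed = _analyzed_mask(topo.shape, template_mask)
    z = topo.heights_nm
    plateau = float(np.median(z[analyzed]))
    depth_map = plateau - z
    binary = (depth_map > 0.5 * min_depth_nm) & analyzed
    labels = measure.label(binary)
    px_nm = topo.pixel_size_nm
    pores = []
    pore_px_total = 0
    for region in measure.regionprops(labels):
        diameter = region.equivalent_diameter_area * px_nm
        if diameter < min_diameter_nm:
            continue
        rmask = labels == region.label
        core = ndimage.binary_erosion(rmask, iterations=2)
        if core.sum() >= 5:
            floor = float(np.median(z[core]))
        else:
            d = depth_map[rmask]
            floor = plateau - float(np.median(d[d >= np.quantile(d, 0.75)]))
        depth = plateau - floor
        if depth < min_depth_nm:
            continue
        pore_px_total += int(rmask.sum())
        pores.append(Pore(centroid_px=tuple(region.centroid),
                          diameter_nm=float(diameter),
                          depth_nm=float(depth),
                          area_nm2=float(region.area * px_nm ** 2)))
    area_um2 = analyzed.sum() * (px_nm / 1000.0) ** 2
    fraction = pore_px_total / analyzed.sum() if analyzed.sum() else 0.0
    return PoreSet(pores=pores, analyzed_area_um2=float(area_um2),
                   pore_area_fraction=float(fraction))


# ---------------------------------------------------------------------------
# particles
# ---------------------------------------------------------------------------

def _class_label(height_nm, gate):
    lo, hi = gate
    band = (hi - lo) / 3.0
    if height_nm < lo + band:
        return "P1"
    if height_nm < lo + 2 * band:
        return "P2"
    return "P3"


def detect_particles(topo: Topograph,
                     height_gate_nm: tuple = HEIGHT_GATE_NM,
                     diameter_gate_nm: tuple = DIAMETER_GATE_NM,
                     min_height_nm: float = 2.0,
                     smooth_sigma_px: float = 1.0,
                     template_mask: Optional[np.ndarray] = None
                     ) -> ParticleSet:
    """Detect membrane-protruding particles and apply the candidate gates.

    Local maxima above ``min_height_nm`` on a lightly smoothed map seed a
    watershed that separates touching particles.  Per particle: height is
    the peak above the (leveled) membrane plane; diameter is the equivalent
    diameter of the area above half the peak height.  Particles inside the
    height and diameter gates are the protein candidates; sub-classes P1-P3
    are tertile bands of the height gate; detections outside the gates are
    retained with class "unclassified".
    """
    if topo.pixel_size_nm > 5.0:
        raise ValueError("pixel size must be <= 5 nm to resolve 10-20 nm "
                         "particles")
    if not topo.leveled:
        warnings.warn("detect_particles expects a leveled topograph")
    analyzed = _analyzed_mask(topo.shape, template_mask)
    z = topo.heights_nm
    zs = ndimage.gaussian_filter(z, smooth_sigma_px)
    min_sep_px = max(int(diameter_gate_nm[0] / topo.pixel_size_nm) // 2, 1)
    peaks = feature.peak_local_max(zs, min_distance=min_sep_px,
                                   threshold_abs=min_height_nm,
                                   exclude_border=2)
    px_nm = topo.pixel_size_nm
    particles = []
    if len(peaks):
        markers = np.zeros(z.shape, dtype=np.int32)
        for i, (py, px) in enumerate(peaks, start=1):
            markers[py, px] = i
        above = zs > 0.25 * min_height_nm
        ws = segmentation.watershed(-zs, markers=markers, mask=above)
        for i, (py, px) in enumerate(peaks, start=1):
            if not analyzed[py, px]:
                continue
            rmask = ws == i
            # height from the raw leveled map: smoothing biases the peak of
            # a curved cap low by ~2 h sigma^2 / a^2
            h = float(z[py, px])
            half = rmask & (zs >= 0.5 * zs[py, px])
            diameter = 2.0 * np.sqrt(half.sum() / np.pi) * px_nm
            gated = (height_gate_nm[0] <= h <= height_gate_nm[1]
                     and diameter_gate_nm[0] <= diameter
                     <= diameter_gate_nm[1])
            label = _class_label(h, height_gate_nm) if gated \
                else "unclassified"
            particles.append(Particle(centroid_px=(int(py), int(px)),
                                      height_nm=h, diameter_nm=float(diameter),
                                      gated=gated, class_label=label))
    area_um2 = analyzed.sum() * (px_nm / 1000.0) ** 2
    return ParticleSet(particles=particles, analyzed_area_um2=float(area_um2),
                       height_gate_nm=height_gate_nm,
                       diameter_gate_nm=diameter_gate_nm)


def attribute_density(test: ParticleSet, control: ParticleSet):
    """Share of test-sample particles attributable to membrane proteins.

    attributable fraction = (rho_test - rho_control) / rho_test and the
    protein density is rho_test - rho_control (particles per um^2).  A
    control density exceeding the test density yields a flagged negative
    result (warning), not an error.
    """
    rho_t = test.density_per_um2
    rho_c = control.density_per_um2
    if rho_t <= 0:
        raise ValueError("test sample has zero particle density")
    fraction = (rho_t - rho_c) / rho_t
    density = rho_t - rho_c
    if rho_c > rho_t:
        warnings.warn("control density exceeds test density; attributable "
                      "fraction is negative")
    return float(fraction), float(density)
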