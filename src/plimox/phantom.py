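"""Synthetic retinal vascular phantom with ground-truth oxygen tension.

The phantom emulates a mouse-retina field of view as seen by a
point-scanning lifetime ophthalmoscope: a couple of major arterioles in
the superficial vascular plexus, a central draining venule, and a bed of
capillaries at depth, each vessel carrying a known pO2.  A single-parameter
Gaussian depth-sectioning weight stands in for the tunable-lens focal
scan + pinhole of the real instrument; the true axial response of such a
system is aberration-dominated and not modelled here.

Coordinates: pixel indices are 0-based (row, col); physical positions are
micrometres; depth is micrometres below the retinal surface, positive
downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VESSEL_CLASSES",
    "VesselSpec",
    "PhantomConfig",
    "Phantom",
    "SectioningModel",
    "generate_phantom",
    "render_scene",
]

VESSEL_CLASSES = ("arteriole", "venule", "capillary")


@dataclass(frozen=True)
class VesselSpec:
    """One vessel: a constant-radius tube along a 2-D polyline centerline."""

    vessel_id: int
    vessel_class: str
    centerline: np.ndarray        # (n, 2) points, micrometres, (row, col)
    radius: float                 # micrometres
    depth: float                  # micrometres below the surface
    true_po2: float               # mmHg

    def __post_init__(self) -> None:
        if self.vessel_class not in VESSEL_CLASSES:
            raise ValueError(f"unknown vessel class {self.vessel_class!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.true_po2 <= 160.0:
            raise ValueError("true_po2 must lie in [0, 160] mmHg")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 2 or cl.shape[0] < 2:
            raise ValueError("centerline must be an (n>=2, 2) point array")
        object.__setattr__(self, "centerline", cl)


def _default_po2_ranges() -> dict:
    # Arterioles carry near-arterial blood; venules sit well below them.
    return {"arteriole": (60.0, 90.0), "venule": (20.0, 45.0),
            "capillary": (35.0, 60.0)}


def _default_depth_ranges() -> dict:
    # Superficial arterioles; capillaries and post-capillary venules deep.
    return {"arteriole": (5.0, 20.0), "venule": (45.0, 65.0),
            "capillary": (40.0, 70.0)}


def _default_radius_ranges() -> dict:
    return {"arteriole": (8.0, 12.0), "venule": (10.0, 16.0),
            "capillary": (2.5, 4.0)}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic scene.

    The default 256x256 grid at 2 um/pixel gives a ~0.5 mm field of view
    about the optic nerve head with two major arterioles, one central
    venule, and a capillary bed, mirroring the geometry the instrument
    images.
    """

    grid_shape: tuple = (256, 256)
    pixel_pitch: float = 2.0                   # um / pixel
    n_arterioles: int = 2
    n_venules: int = 1
    n_capillaries: int = 20
    po2_ranges: dict = field(default_factory=_default_po2_ranges)
    depth_ranges: dict = field(default_factory=_default_depth_ranges)
    radius_ranges: dict = field(default_factory=_default_radius_ranges)
    background_intensity: float = 0.0          # relative units
    temperature: float = 36.7                  # degC

    def __post_init__(self) -> None:
        if min(self.grid_shape) <= 0:
            raise ValueError("grid_shape must be positive")
        if self.n_arterioles < 1 or self.n_venules < 1 or self.n_capillaries < 1:
            raise ValueError("at least one vessel per class is required")
        for name, rng in (("po2_ranges", self.po2_ranges),
                          ("depth_ranges", self.depth_ranges),
                          ("radius_ranges", self.radius_ranges)):
            for cls in VESSEL_CLASSES:
                lo, hi = rng[cls]
                if lo > hi:
                    raise ValueError(f"{name}[{cls!r}]: min > max")


@dataclass(frozen=True)
class Phantom:
    grid_shape: tuple
    pixel_pitch: float
    vessels: Sequence[VesselSpec]
    background_intensity: float
    temperature: float
    seed: int | None = None

    @property
    def fov_um(self) -> tuple:
        ny, nx = self.grid_shape
        return (ny * self.pixel_pitch, nx * self.pixel_pitch)


@dataclass(frozen=True)
class SectioningModel:
    """Gaussian depth-sectioning weight: w(z) = exp(-(z - z_f)^2 / 2 sigma^2).

    ``sectioning_sigma`` is the axial weight scale in micrometres; the
    weight is 1 exactly at the focal depth and falls off symmetrically.
    """

    focal_depth: float           # um
    sectioning_sigma: float = 15.0

    def __post_init__(self) -> None:
        if self.sectioning_sigma <= 0:
            raise ValueError("sectioning_sigma must be positive")

    def weight(self, depth) -> np.ndarray:
        z = np.asarray(depth, dtype=float)
        w = np.exp(-((z - self.focal_depth) ** 2)
                   / (2.0 * self.sectioning_sigma**2))
        return w if w.ndim else float(w)

    def at(self, focal_depth: float) -> "SectioningModel":
        return replace(self, focal_depth=focal_depth)


def _wavy_line(rng, row_frac: float, fov: tuple, n_pts: int = 24,
               wobble: float = 0.02) -> np.ndarray:
    """Roughly horizontal major-vessel centerline spanning the full width."""
    h, w = fov
    cols = np.linspace(0.0, w, n_pts)
    rows = row_frac * h + np.cumsum(rng.normal(0.0, wobble * h, n_pts))
    rows -= rows.mean() - row_frac * h
    rows = np.clip(rows, 0.0, h)
    return np.column_stack([rows, cols])


def _capillary_walk(rng, start: np.ndarray, end: np.ndarray, fov: tuple,
                    n_pts: int = 16, wobble: float = 0.025) -> np.ndarray:
    """Smooth random walk from an arteriole point toward a venule point."""
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    base = (1 - t) * start[None, :] + t * end[None, :]
    noise = rng.normal(0.0, wobble * min(fov), (n_pts, 2))
    noise[0] = noise[-1] = 0.0
    # cheap smoothing of the jitter so capillaries meander, not zigzag
    kern = np.array([0.25, 0.5, 0.25])
    for _ in range(2):
        noise = np.apply_along_axis(
            lambda v: np.convolve(v, kern, mode="same"), 0, noise)
    pts = base + noise
    pts[:, 0] = np.clip(pts[:, 0], 0.0, fov[0])
    pts[:, 1] = np.clip(pts[:, 1], 0.0, fov[1])
    return pts


def generate_phantom(config: PhantomConfig | None = None,
                     seed: int = 0) -> Phantom:
    """Build a seeded synthetic vascular scene.

    Major vessels are interleaved across the field (arterioles flanking
    the central venule(s)); capillaries run between random points on an
    arteriole and a venule.  Per-class pO2, depth and radius are drawn
    uniformly from the configured ranges; with the default disjoint pO2
    ranges every arteriole is better oxygenated than every venule.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    fov = (config.grid_shape[0] * config.pixel_pitch,
           config.grid_shape[1] * config.pixel_pitch)

    # interleave major vessels: venules central, arterioles outward
    n_major = config.n_arterioles + config.n_venules
    fracs = np.linspace(0.15, 0.85, n_major)
    order = np.argsort(np.abs(fracs - 0.5))
    venule_fracs = fracs[order[:config.n_venules]]
    arteriole_fracs = fracs[order[config.n_venules:]]

    vessels: list[VesselSpec] = []
    vid = 1

    def draw(cls, rng_map):
        lo, hi = rng_map[cls]
        return float(rng.uniform(lo, hi))

    arterioles, venules = [], []
    for frac in np.sort(arteriole_fracs):
        cl = _wavy_line(rng, frac, fov)
        v = VesselSpec(vid, "arteriole", cl,
                       draw("arteriole", config.radius_ranges),
                       draw("arteriole", config.depth_ranges),
                       draw("arteriole", config.po2_ranges))
        arterioles.append(v)
        vessels.append(v)
        vid += 1
    for frac in np.sort(venule_fracs):
        cl = _wavy_line(rng, frac, fov)
        v = VesselSpec(vid, "venule", cl,
                       draw("venule", config.radius_ranges),
                       draw("venule", config.depth_ranges),
                       draw("venule", config.po2_ranges))
        venules.append(v)
        vessels.append(v)
        vid += 1
    for _ in range(config.n_capillaries):
        a = arterioles[rng.integers(len(arterioles))]
        v = venules[rng.integers(len(venules))]
        start = a.centerline[rng.integers(a.centerline.shape[0])]
        end = v.centerline[rng.integers(v.centerline.shape[0])]
        cl = _capillary_walk(rng, start, end, fov)
        vessels.append(VesselSpec(vid, "capillary", cl,
                                  draw("capillary", config.radius_ranges),
                                  draw("capillary", config.depth_ranges),
                                  draw("capillary", config.po2_ranges)))
        vid += 1

    return Phantom(grid_shape=tuple(config.grid_shape),
                   pixel_pitch=config.pixel_pitch,
                   vessels=tuple(vessels),
                   background_intensity=config.background_intensity,
                   temperature=config.temperature,
                   seed=seed)


def _dist_to_polyline(py: np.ndarray, px: np.ndarray,
                      line: np.ndarray) -> np.ndarray:
    """Minimum distance from each pixel centre to a polyline (um)."""
    p = np.stack([py.ravel(), px.ravel()], axis=1)          # (m, 2)
    a = line[:-1]                                            # (s, 2)
    b = line[1:]
    ab = b - a                                               # (s, 2)
    denom = (ab**2).sum(axis=1)
    denom[denom == 0] = 1.0
    # project every pixel onto every segment
    ap = p[:, None, :] - a[None, :, :]                       # (m, s, 2)
    t = np.clip((ap * ab[None, :, :]).sum(-1) / denom[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.sqrt(((p[:, None, :] - closest) ** 2).sum(-1)).min(axis=1)
    return d.reshape(py.shape)


def render_scene(phantom: Phantom, sectioning: SectioningModel):
    """Rasterize the phantom at a focal depth.

    Returns ``(label_map, weight_map, po2_map_truth)``.  Each pixel is
    owned by at most one vessel; where tubes overlap the vessel closest to
    the focal plane wins, so a single truth value exists per pixel (the
    out-of-focus vessel is still "visible" in a real image, but only as
    background haze).  ``po2_map_truth`` is NaN off-vessel.
    """
    ny, nx = phantom.grid_shape
    pitch = phantom.pixel_pitch
    py, px = np.meshgrid((np.arange(ny) + 0.5) * pitch,
                         (np.arange(nx) + 0.5) * pitch, indexing="ij")

    label = np.zeros((ny, nx), dtype=np.int32)
    weight = np.zeros((ny, nx), dtype=float)
    po2 = np.full((ny, nx), np.nan)
    owner_focus_dist = np.full((ny, nx), np.inf)

    for v in phantom.vessels:
        inside = _dist_to_polyline(py, px, v.centerline) <= v.radius
        focus_dist = abs(v.depth - sectioning.focal_depth)
        take = inside & (focus_dist < owner_focus_dist)
        label[take] = v.vessel_id
        weight[take] = sectioning.weight(v.depth)
        po2[take] = v.true_po2
        owner_focus_dist[take] = focus_dist

    return label, weight, po2
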