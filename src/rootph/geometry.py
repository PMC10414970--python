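"""Per-frame spatial scaffold.

The root is the dark (dye-excluded) object in a bright stained medium, so
segmentation thresholds the *summed* channels and keeps the largest dark
component.  The midline is the pruned skeleton ordered tip-first with
cumulative arc length; the surface band is the set of medium pixels whose
Euclidean distance to the mask lies in [band_min_px, band_max_px], each
carrying a longitudinal coordinate (arc length from the tip of the
nearest midline point) and a left/right side label.

Coordinates are (y, x) with pixel centers at integers and y increasing
downward; the default gravity vector is +y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import filters, morphology

from .config import RunConfig
from .errors import (
    DegenerateTopologyError,
    NoRootFoundError,
    ShortRootError,
    StainingFailureError,
)

logger = logging.getLogger("rootph")

#: number of midline points used for the tip-tangent least-squares fit
TIP_FIT_POINTS = 25


@dataclass
class RootGeometry:
    """Spatial scaffold of one frame.

    ``midline`` is an (N, 2) float array of (y, x) points ordered from
    the tip (index 0) shootward; ``arc_s_um`` the matching cumulative
    arc length (0 at the tip); ``tip_tangent`` a unit (dy, dx) vector
    pointing rootward (away from the shoot).
    """

    mask: np.ndarray
    midline: np.ndarray
    arc_s_um: np.ndarray
    tip: np.ndarray
    tip_tangent: np.ndarray
    pixel_size_um: float = 1.0

    @property
    def length_um(self) -> float:
        return float(self.arc_s_um[-1])


@dataclass
class SurfaceBand:
    """Medium pixels 10-25 px off the root surface, with coordinates.

    ``side`` is +1 (left of the midline when looking tipward) or -1
    (right); intensities are background-subtracted.
    """

    yx: np.ndarray          # (N, 2) int pixel coordinates
    dist_px: np.ndarray     # Euclidean distance to the mask
    s_um: np.ndarray        # arc length from tip of nearest midline point
    side: np.ndarray        # +1 left / -1 right
    i488: np.ndarray
    i405: np.ndarray
    offset_yx: np.ndarray = None  # displacement from nearest midline point

    def __len__(self) -> int:
        return len(self.s_um)

    def select(self, sel: np.ndarray) -> "SurfaceBand":
        return SurfaceBand(
            self.yx[sel], self.dist_px[sel], self.s_um[sel],
            self.side[sel], self.i488[sel], self.i405[sel],
            self.offset_yx[sel] if self.offset_yx is not None else None,
        )


def segment_root(frame: np.ndarray, config: Optional[RunConfig] = None) -> np.ndarray:
    """Segment the dark root from the bright medium.

    Thresholds the summed channels (Otsu after pseudo-flat-field
    normalization), takes dark pixels, applies a morphological closing,
    fills holes, removes components below ``min_area_px`` and keeps the
    largest remaining one.
    """
    config = config or RunConfig()
    frame = np.asarray(frame, dtype=float)
    summed = frame[0] + frame[1]
    if summed.max() == summed.min():
        raise NoRootFoundError("image is uniform; no dark root present")
    if config.flatfield_sigma_px > 0:
        # pseudo-flat-field: normalize by the image's own coarse structure so
        # smooth illumination gradients do not bleed into the threshold
        blur = ndimage.gaussian_filter(summed, config.flatfield_sigma_px)
        summed = summed / np.maximum(blur, 1e-12)
    thr = filters.threshold_otsu(summed)
    # intermeans refinement: histogram-based Otsu returns the first index of
    # a plateau, which can sit flush against the dark cluster; iterate the
    # threshold to the midpoint of the two class means
    for _ in range(20):
        dark_mean = summed[summed < thr].mean()
        bright_mean = summed[summed >= thr].mean()
        new_thr = 0.5 * (dark_mean + bright_mean)
        if abs(new_thr - thr) < 1e-9:
            break
        thr = new_thr
    dark = summed < thr
    if dark.mean() > 0.8:
        raise StainingFailureError(
            f"{dark.mean():.0%} of the image is dark; medium appears unstained"
        )
    if config.closing_radius_px > 0:
        dark = morphology.closing(dark, morphology.disk(config.closing_radius_px))
    dark = ndimage.binary_fill_holes(dark)
    labels, n = ndimage.label(dark)  # 4-connectivity by default
    if n == 0:
        raise NoRootFoundError("no dark component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < config.min_area_px:
        raise NoRootFoundError(
            f"largest dark component ({int(sizes[best - 1])} px) below "
            f"min_area_px={config.min_area_px}"
        )
    return labels == best


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    ys, xs = np.nonzero(skel)
    pts = set(zip(ys.tolist(), xs.tolist()))
    g = nx.Graph()
    g.add_nodes_from(pts)
    for y, x in pts:
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                q = (y + dy, x + dx)
                if q in pts:
                    g.add_edge((y, x), q, weight=float(np.hypot(dy, dx)))
    return g


def extract_midline(mask: np.ndarray) -> np.ndarray:
    """Skeletonize the mask and return its longest path as (N, 2) points.

    The longest geodesic path between skeleton endpoints is kept, which
    prunes side branches; raises on loop-only or point-like skeletons.
    """
    skel = morphology.skeletonize(mask)
    if skel.sum() < 2:
        raise DegenerateTopologyError("skeleton degenerate (fewer than 2 pixels)")
    g = _skeleton_graph(skel)
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if len(endpoints) < 2:
        raise DegenerateTopologyError(
            "skeleton has no endpoint pair (loop or point); cannot define a midline"
        )
    # tree-diameter heuristic: farthest endpoint from an arbitrary endpoint,
    # then farthest from that one
    dist = nx.single_source_dijkstra_path_length(g, endpoints[0], weight="weight")
    a = max(endpoints, key=lambda n: dist.get(n, -1.0))
    dist_a, paths_a = nx.single_source_dijkstra(g, a, weight="weight")
    b = max(endpoints, key=lambda n: dist_a.get(n, -1.0))
    path = paths_a[b]
    return np.asarray(path, dtype=float)


def detect_tip(
    midline: np.ndarray,
    mask: np.ndarray,
    gravity_vector: np.ndarray,
    border_px: int = 10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Identify which midline endpoint is the tip and its tangent.

    The tip is the endpoint *not* within ``border_px`` of an image
    border (the root enters the field shootward); if both or neither
    touch a border, the endpoint with the largest projection on the
    gravity vector (most "down") wins.  The tangent is the direction of
    a least-squares line through the 25 midline points nearest the tip,
    oriented tipward.  Returns (tip, tangent, tip_is_last).
    """
    if len(midline) < TIP_FIT_POINTS:
        raise ShortRootError(
            f"midline has {len(midline)} points; need >= {TIP_FIT_POINTS}"
        )
    h, w = mask.shape
    ends = np.asarray([midline[0], midline[-1]])

    def border_dist(p):
        return min(p[0], p[1], h - 1 - p[0], w - 1 - p[1])

    d0, d1 = border_dist(ends[0]), border_dist(ends[1])
    g = np.asarray(gravity_vector, float)
    if abs(d0 - d1) > border_px:
        # the endpoint clearly nearer a border is where the root enters the
        # field (shootward); the other one is the tip
        tip_is_last = d1 > d0
    else:
        tip_is_last = (ends[1] @ g) > (ends[0] @ g)
    tip = ends[1] if tip_is_last else ends[0]
    pts = midline[-TIP_FIT_POINTS:] if tip_is_last else midline[:TIP_FIT_POINTS]
    centered = pts - pts.mean(axis=0)
    # principal direction of the tip segment
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    tangent = vt[0]
    inward = pts[-1] - pts[0] if tip_is_last else pts[0] - pts[-1]
    if tangent @ inward < 0:
        tangent = -tangent
    return tip, tangent / np.linalg.norm(tangent), tip_is_last


def _extend_to_boundary(
    midline: np.ndarray, tangent: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """March from the tip endpoint along the tangent until leaving the mask.

    Skeletons stop roughly one radius short of the anatomical tip; this
    anchors s = 0 at the mask boundary instead.
    """
    h, w = mask.shape
    p = midline[0].copy()
    extra = []
    for _ in range(512):
        p = p + 0.5 * tangent
        iy, ix = int(round(p[0])), int(round(p[1]))
        if not (0 <= iy < h and 0 <= ix < w) or not mask[iy, ix]:
            break
        extra.append(p.copy())
    if extra:
        return np.vstack([np.asarray(extra[::-1]), midline])
    return midline


def _smooth_path(path: np.ndarray, window: int = 9) -> np.ndarray:
    """Moving-average smoothing of an ordered pixel path.

    Raw skeleton paths are staircases whose summed step lengths
    overestimate the arc length of a curved axis; a short uniform filter
    removes the jaggedness without shifting the line.
    """
    if len(path) < window:
        return path
    return ndimage.uniform_filter1d(path, window, axis=0, mode="nearest")


def compute_geometry(
    mask: np.ndarray,
    pixel_size_um: float = 1.0,
    gravity_vector: np.ndarray = np.array([1.0, 0.0]),
) -> RootGeometry:
    """Full scaffold from a mask: midline (tip-first), arc length, tip."""
    midline = extract_midline(mask)
    tip, tangent, tip_is_last = detect_tip(midline, mask, gravity_vector)
    if tip_is_last:
        midline = midline[::-1]
    midline = _smooth_path(midline)
    midline = _extend_to_boundary(midline, tangent, mask)
    steps = np.linalg.norm(np.diff(midline, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)]) * pixel_size_um
    return RootGeometry(
        mask=mask,
        midline=midline,
        arc_s_um=arc,
        tip=midline[0],
        tip_tangent=tangent,
        pixel_size_um=pixel_size_um,
    )


def _midline_tangents(midline: np.ndarray) -> np.ndarray:
    t = np.gradient(midline, axis=0)
    norms = np.linalg.norm(t, axis=1)
    norms[norms == 0] = 1.0
    return t / norms[:, None]


def extract_surface_band(
    geometry: RootGeometry,
    frame: np.ndarray,
    config: Optional[RunConfig] = None,
) -> SurfaceBand:
    """Collect medium pixels 10-25 px (Euclidean) off the root surface.

    Each band pixel carries background-subtracted intensities (negatives
    clamped to 0 with a logged count), the arc length of its nearest
    midline point, and a side label from the sign of the cross product
    of the local midline tangent with the midline-to-pixel vector.
    """
    config = config or RunConfig()
    mask = geometry.mask
    dist = ndimage.distance_transform_edt(~mask)
    sel = (dist >= config.band_min_px) & (dist <= config.band_max_px)
    ys, xs = np.nonzero(sel)
    yx = np.column_stack([ys, xs]).astype(float)

    i488 = frame[0][ys, xs].astype(float) - config.background_488
    i405 = frame[1][ys, xs].astype(float) - config.background_405
    n_clamped = int((i488 < 0).sum() + (i405 < 0).sum())
    if n_clamped:
        logger.info("background subtraction clamped %d negative pixels", n_clamped)
    i488 = np.clip(i488, 0, None)
    i405 = np.clip(i405, 0, None)

    tree = cKDTree(geometry.midline)
    _, idx = tree.query(yx)
    s_um = geometry.arc_s_um[idx]
    tangents = _midline_tangents(geometry.midline)[idx]
    vec = yx - geometry.midline[idx]
    cross = tangents[:, 0] * vec[:, 1] - tangents[:, 1] * vec[:, 0]
    side = np.where(cross >= 0, 1, -1).astype(np.int8)

    band = SurfaceBand(
        yx=np.column_stack([ys, xs]),
        dist_px=dist[ys, xs],
        s_um=s_um,
        side=side,
        i488=i488,
        i405=i405,
        offset_yx=vec,
    )
    _warn_if_clipped(band, geometry, config)
    return band


def _warn_if_clipped(band: SurfaceBand, geometry: RootGeometry, config: RunConfig) -> None:
    """Non-fatal boundary warning when the band is cut by the image edge."""
    h, w = geometry.mask.shape
    margin = config.band_max_px
    near_edge = (
        (band.yx[:, 0] < margin) | (band.yx[:, 0] >= h - margin)
        | (band.yx[:, 1] < margin) | (band.yx[:, 1] >= w - margin)
    )
    if len(band) and near_edge.mean() > 0.3:
        logger.warning(
            "surface band clipped by the image border over %.0f%% of its pixels",
            100 * near_edge.mean(),
        )
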