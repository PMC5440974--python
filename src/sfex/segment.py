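"""Segmentation of the enhanced map into unbranched filament fragments.

The enhanced (OFT) map is binarized with Otsu's threshold, skeletonized
to 1-px-wide centerlines, and partitioned into unbranched *fragments* by
deleting junction regions — skeleton pixels whose 8-neighborhood holds
three or more skeleton pixels, together with their immediate skeleton
neighbors.  Each remaining connected component is traced end-to-end into
an ordered pixel chain; a propagation direction is attached to each of
its two termini (pointing from the local center of mass of the chain
toward the tip), which is the geometry the reconstruction stage pairs on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from ._util import direction_deg

__all__ = [
    "SegmentParams",
    "FilamentFragment",
    "binarize",
    "skeletonize_and_fragment",
    "fragments_to_csv",
    "fragments_to_labels",
]

#: length of the chain tail (px) whose center of mass anchors the
#: propagation direction at a terminus
DIRECTION_WINDOW = 10

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


@dataclass
class SegmentParams:
    """threshold_method is Otsu; ``multiplier`` scales the Otsu level;
    fragments shorter than ``min_fragment_length`` px are discarded."""

    multiplier: float = 1.0
    min_fragment_length: int = 5

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if self.min_fragment_length < 2:
            raise ValueError("min_fragment_length must be >= 2")


@dataclass
class FilamentFragment:
    """An unbranched, ordered 8-connected pixel chain.

    ``direction_a`` / ``direction_b`` are the propagation directions in
    degrees (-180, 180]: from the center of mass of the chain tail nearest
    each terminus toward that terminus.  Terminus A is the endpoint with
    the smaller (row, col).
    """

    id: int
    pixels: np.ndarray  # (n, 2) int, ordered A -> B
    center_of_mass: tuple[float, float]
    direction_a: float
    direction_b: float

    @property
    def terminus_a(self) -> tuple[int, int]:
        return tuple(self.pixels[0])

    @property
    def terminus_b(self) -> tuple[int, int]:
        return tuple(self.pixels[-1])

    def __len__(self) -> int:
        return len(self.pixels)


def binarize(oft_map: np.ndarray, params: SegmentParams | None = None) -> np.ndarray:
    """Threshold the enhanced map at ``multiplier x`` the Otsu level.

    The Otsu level is computed on a 256-bin histogram over the map's value
    range; the mask is ``map >= threshold``.  A constant map yields an
    empty mask with a warning.
    """
    params = params or SegmentParams()
    oft_map = np.asarray(oft_map, dtype=float)
    if not np.all(np.isfinite(oft_map)):
        raise ValueError("map must contain finite values")
    if oft_map.min() == oft_map.max():
        warnings.warn("constant map: empty mask", stacklevel=2)
        return np.zeros(oft_map.shape, dtype=bool)
    level = otsu_threshold(oft_map)
    return oft_map >= params.multiplier * level


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold on a 256-bin histogram over the value range.

    The inter-class variance can be flat-maximal over a run of empty bins
    (e.g. well-separated modes); the midpoint of that plateau is returned
    so the level sits between the modes rather than at the first empty
    bin.
    """
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(float)
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    m = np.cumsum(hist * centers)
    mu0 = m[:-1] / np.where(w0 > 0, w0, np.nan)
    mu1 = (m[-1] - m[:-1]) / np.where(w1 > 0, w1, np.nan)
    var = w0 * w1 * (mu0 - mu1) ** 2
    var = np.where(np.isfinite(var), var, -np.inf)
    best = var.max()
    # empty bins leave the variance bitwise unchanged, so exact ties mark
    # the flat valley between separated modes
    plateau = np.nonzero(var == best)[0]
    # threshold between bin k and k+1 -> use the midpoint of the plateau
    k = int(round(plateau.mean()))
    return float(centers[k])


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL,
                            mode="constant", cval=0)


#: a surviving component whose every pixel lies within this distance (px)
#: of a deleted branch point is junction debris, not a filament arm
JUNCTION_DEBRIS_RADIUS = 5.0


def _remove_junctions(skel: np.ndarray) -> np.ndarray:
    """Delete junction regions from a skeleton.

    Branch points (>= 3 skeleton neighbors) are removed together with
    their skeleton neighbors; residual branch points are re-checked until
    every pixel has <= 2 neighbors.  Where two filaments cross at a
    shallow angle the skeleton contains a short connector between the two
    branch points of the crossing; such debris — components that never
    leave the neighborhood of a branch point — belongs to the junction
    region and is removed as well.
    """
    skel = skel.copy()
    junctions = skel & (_neighbor_counts(skel) >= 3)
    if junctions.any():
        # junction *regions*: the branch pixels plus their 8-neighbors
        grown = ndimage.binary_dilation(junctions, structure=np.ones((3, 3)))
        skel &= ~grown
    while True:
        residual = skel & (_neighbor_counts(skel) >= 3)
        if not residual.any():
            break
        skel &= ~residual
    if junctions.any():
        far = ndimage.distance_transform_edt(~junctions) > JUNCTION_DEBRIS_RADIUS
        labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
        if n:
            escapes = ndimage.sum(far, labels, index=np.arange(1, n + 1))
            debris = np.isin(labels, np.nonzero(escapes == 0)[0] + 1)
            skel &= ~debris
    return skel


def _trace_chain(coords: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order a degree-<=2 8-connected component end-to-end.

    Starts at an endpoint (degree-1 pixel); a cycle (no endpoint) is broken
    at its smallest (row, col) pixel.  4-adjacent neighbors are preferred
    over diagonal ones when both are available.
    """
    def neighbors(p):
        r, c = p
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in coords:
                    out.append(q)
        return out

    endpoints = sorted(p for p in coords if len(neighbors(p)) <= 1)
    start = endpoints[0] if endpoints else min(coords)
    chain = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [q for q in neighbors(cur) if q not in visited]
        if not nxt:
            break
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
        chain.append(cur)
        visited.add(cur)
    return chain


def _tip_direction(pixels: np.ndarray, tip_index: int) -> float:
    """Direction from the local center of mass of the chain tail toward the
    terminus at ``tip_index`` (0 or -1)."""
    n = len(pixels)
    w = min(n, DIRECTION_WINDOW)
    tail = pixels[:w] if tip_index == 0 else pixels[-w:]
    com = tail.mean(axis=0)
    tip = pixels[tip_index].astype(float)
    return direction_deg(tip[0] - com[0], tip[1] - com[1])


def skeletonize_and_fragment(mask: np.ndarray,
                             params: SegmentParams | None = None
                             ) -> list[FilamentFragment]:
    """Skeletonize a binary mask and split it into unbranched fragments."""
    params = params or SegmentParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    skel = skeletonize(mask)
    skel = _remove_junctions(skel)
    labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
    fragments: list[FilamentFragment] = []
    objs = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objs[lab - 1]
        rr, cc = np.nonzero(labels[sl] == lab)
        coords = {(int(r + sl[0].start), int(c + sl[1].start))
                  for r, c in zip(rr, cc)}
        if len(coords) < params.min_fragment_length:
            continue
        chain = _trace_chain(coords)
        if len(chain) < len(coords):
            # tracing could not cover the component in one path; skip the
            # leftover (tiny 8-connectivity artifacts)
            coords = set(chain)
            if len(coords) < params.min_fragment_length:
                continue
        pixels = np.asarray(chain, dtype=int)
        if tuple(pixels[-1]) < tuple(pixels[0]):
            pixels = pixels[::-1].copy()
        frag = FilamentFragment(
            id=len(fragments),
            pixels=pixels,
            center_of_mass=tuple(pixels.mean(axis=0)),
            direction_a=_tip_direction(pixels, 0),
            direction_b=_tip_direction(pixels, -1),
        )
        fragments.append(frag)
    return fragments


def fragments_to_csv(fragments: list[FilamentFragment]) -> pd.DataFrame:
    rows = [(f.id, i, int(r), int(c))
            for f in fragments for i, (r, c) in enumerate(f.pixels)]
    return pd.DataFrame(rows, columns=["fragment_id", "point_index", "row", "col"])


def fragments_to_labels(fragments: list[FilamentFragment],
                        shape: tuple[int, int]) -> np.ndarray:
    """Label image with fragment id + 1 at fragment pixels, 0 elsewhere."""
    out = np.zeros(shape, dtype=np.int32)
    for f in fragments:
        out[f.pixels[:, 0], f.pixels[:, 1]] = f.id + 1
    return out
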