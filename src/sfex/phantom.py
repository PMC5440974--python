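"""Synthetic filament phantoms for benchmarking the extraction pipeline.

A phantom scene is a set of parametric ground-truth filament paths
(circular arcs, straight segments, polylines) rasterized onto a pixel
grid, convolved with a Gaussian point-spread function, and optionally
corrupted with additive Gaussian read-out noise at a requested peak
signal-to-noise ratio (PSNR).  Default physical scales emulate
TIRF microscopy of F-actin: pixel size 108 nm, PSF sigma 72 nm.

PSNR is defined as ``20 * log10(peak(clean) / sigma_noise)`` in dB.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "ArcPath",
    "SegmentPath",
    "PolylinePath",
    "PhantomSpec",
    "PhantomScene",
    "make_phantom",
    "corrupt",
    "compute_psnr",
    "default_benchmark_spec",
    "default_benchmark_scene",
    "save_scene",
]

#: sub-pixel sampling step (px) used when rasterizing parametric paths;
#: fine enough that every pixel the continuous path passes through is hit
RASTER_STEP = 0.05

#: sentinel PSNR for a noise-free image
CLEAN = math.inf


@dataclass(frozen=True)
class ArcPath:
    """Circular arc: ``center`` (row, col) px, ``radius`` px, angular span
    ``theta_start`` → ``theta_end`` in degrees (package angle convention)."""

    center: tuple[float, float]
    radius: float
    theta_start: float
    theta_end: float

    def length(self) -> float:
        return abs(math.radians(self.theta_end - self.theta_start)) * self.radius

    def sample(self, step: float = RASTER_STEP) -> np.ndarray:
        n = max(2, int(math.ceil(self.length() / step)) + 1)
        ang = np.radians(np.linspace(self.theta_start, self.theta_end, n))
        rows = self.center[0] - self.radius * np.sin(ang)
        cols = self.center[1] + self.radius * np.cos(ang)
        return np.column_stack([rows, cols])


@dataclass(frozen=True)
class SegmentPath:
    """Straight segment between two (row, col) endpoints, px."""

    start: tuple[float, float]
    end: tuple[float, float]

    def length(self) -> float:
        return math.dist(self.start, self.end)

    def sample(self, step: float = RASTER_STEP) -> np.ndarray:
        n = max(2, int(math.ceil(self.length() / step)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        p0 = np.asarray(self.start, dtype=float)
        p1 = np.asarray(self.end, dtype=float)
        return p0 + t * (p1 - p0)


@dataclass(frozen=True)
class PolylinePath:
    """Piecewise-linear path through a list of (row, col) vertices, px."""

    points: tuple[tuple[float, float], ...]

    def length(self) -> float:
        pts = np.asarray(self.points, dtype=float)
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))

    def sample(self, step: float = RASTER_STEP) -> np.ndarray:
        segs = [SegmentPath(tuple(a), tuple(b)).sample(step)
                for a, b in zip(self.points[:-1], self.points[1:])]
        out = [segs[0]]
        out.extend(s[1:] for s in segs[1:])
        return np.vstack(out)


@dataclass
class PhantomSpec:
    """Recipe for a synthetic micrograph.

    Parameters
    ----------
    image_shape : (rows, cols) in px.
    filaments : list of ArcPath / SegmentPath / PolylinePath.
    pixel_size : physical pixel size, nm/px.
    psf_sigma : Gaussian PSF sigma, nm.
    peak_intensity : intensity at the brightest pixel of the clean image.
    psnr : requested PSNR in dB, or None for a clean image.
    seed : seed for the noise generator; fully determines the noisy image.
    """

    image_shape: tuple[int, int]
    filaments: list = field(default_factory=list)
    pixel_size: float = 108.0
    psf_sigma: float = 72.0
    peak_intensity: float = 100.0
    intensities: list[float] | None = None  # per-filament relative brightness
    psnr: float | None = None
    seed: int = 0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    def validate(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")
        if self.peak_intensity <= 0:
            raise ValueError("peak_intensity must be positive")
        if self.psnr is not None and self.psnr <= 0:
            raise ValueError("psnr must be positive (or None for clean)")
        if self.intensities is not None:
            if len(self.intensities) != len(self.filaments):
                raise ValueError("one relative intensity per filament required")
            if min(self.intensities) <= 0:
                raise ValueError("relative intensities must be positive")
        margin = math.ceil(3.0 * self.psf_sigma_px)
        h, w = self.image_shape
        for k, fil in enumerate(self.filaments):
            pts = fil.sample()
            if (pts[:, 0].min() < margin or pts[:, 0].max() > h - 1 - margin
                    or pts[:, 1].min() < margin or pts[:, 1].max() > w - 1 - margin):
                raise ValueError(
                    f"filament {k} extends outside the image bounds "
                    f"(PSF rendering margin {margin} px)")


@dataclass
class PhantomScene:
    """A rendered phantom: ground truth plus clean and noisy images."""

    spec: PhantomSpec
    truth_paths: list[np.ndarray]
    truth_skeleton: np.ndarray
    clean_image: np.ndarray
    noisy_image: np.ndarray
    achieved_psnr: float

    @property
    def image(self) -> np.ndarray:
        """The image downstream stages should analyze (noisy if present)."""
        return self.noisy_image


def rasterize(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-pixel rasterization of a subpixel path; returns a bool grid."""
    grid = np.zeros(shape, dtype=bool)
    idx = np.round(points).astype(int)
    grid[idx[:, 0], idx[:, 1]] = True
    return grid


def make_phantom(spec: PhantomSpec) -> PhantomScene:
    """Render a phantom scene from its spec.

    The clean image is the unit-intensity rasterized skeleton convolved
    with the PSF Gaussian and rescaled so its maximum equals
    ``peak_intensity``.  Noise is applied by :func:`corrupt` when
    ``spec.psnr`` is set.
    """
    spec.validate()
    shape = tuple(spec.image_shape)
    skeleton = np.zeros(shape, dtype=bool)
    density = np.zeros(shape, dtype=float)
    weights = spec.intensities or [1.0] * len(spec.filaments)
    truth_paths = []
    for fil, w in zip(spec.filaments, weights):
        pts = fil.sample()
        truth_paths.append(pts)
        mask = rasterize(pts, shape)
        skeleton |= mask
        density += w * mask  # fluorophore density adds where filaments cross

    clean = gaussian_filter(density, spec.psf_sigma_px)
    if clean.max() > 0:
        clean *= spec.peak_intensity / clean.max()

    if spec.psnr is None:
        noisy, achieved = clean.copy(), CLEAN
    else:
        noisy, achieved = corrupt(clean, spec.psnr, spec.seed)
    return PhantomScene(spec, truth_paths, skeleton, clean, noisy, achieved)


def corrupt(clean: np.ndarray, psnr: float, seed: int) -> tuple[np.ndarray, float]:
    """Add zero-mean Gaussian noise at the requested PSNR (dB).

    The noise standard deviation is ``peak(clean) / 10**(psnr/20)``; the
    drawn field is rescaled to that exact sample standard deviation so the
    achieved PSNR matches the request.  The same seed gives a bitwise
    identical result.
    """
    if psnr <= 0:
        raise ValueError("psnr must be positive")
    peak = float(clean.max())
    if peak <= 0:
        raise ValueError("clean image must have a positive peak")
    sigma = peak / 10.0 ** (psnr / 20.0)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(clean.shape)
    noise *= sigma / noise.std()
    noisy = clean + noise
    return noisy, compute_psnr(clean, noisy)


def compute_psnr(clean: np.ndarray, noisy: np.ndarray) -> float:
    """PSNR (dB) of ``noisy`` against ``clean``; +inf for identical images."""
    if clean.shape != noisy.shape:
        raise ValueError("images must have the same shape")
    resid = np.std(noisy - clean)
    if resid == 0:
        return CLEAN
    return float(20.0 * np.log10(clean.max() / resid))


# ---------------------------------------------------------------------------
# Default benchmark scene
# ---------------------------------------------------------------------------
#
# Nine filaments (arcs and straight chords) on a 256 x 256 grid, 27.6 um
# across at 108 nm/px.  The arrangement emulates a stereotypical adherent
# cell: transverse arcs with curvature radii of 4-11 um in the protrusive
# half, flanked and crossed by long straight ventral fibers.  Coordinates
# are fixed constants so that benchmarks are reproducible.

BENCHMARK_SHAPE = (256, 256)

BENCHMARK_FILAMENTS = (
    # three concentric transverse arcs (curvature radii 7.6-11.9 um)
    ArcPath(center=(150.0, 128.0), radius=110.0, theta_start=60.0, theta_end=120.0),
    ArcPath(center=(160.0, 128.0), radius=90.0, theta_start=55.0, theta_end=125.0),
    ArcPath(center=(170.0, 128.0), radius=70.0, theta_start=50.0, theta_end=140.0),
    # rear arc
    ArcPath(center=(235.0, 128.0), radius=80.0, theta_start=40.0, theta_end=140.0),
    # long ventral fibers; S3/S4 cross all four arcs, S5 crosses S1
    SegmentPath(start=(30.0, 50.0), end=(230.0, 38.0)),
    SegmentPath(start=(30.0, 210.0), end=(230.0, 220.0)),
    SegmentPath(start=(12.0, 148.0), end=(230.0, 165.0)),
    SegmentPath(start=(12.0, 102.0), end=(230.0, 88.0)),
    SegmentPath(start=(152.0, 25.0), end=(146.0, 72.0)),
)

#: relative brightness of each benchmark filament; real stress fibers span
#: roughly a two-fold intensity range, transverse arcs dimmer than the
#: thick ventral fibers
BENCHMARK_INTENSITIES = (0.65, 0.8, 0.6, 0.9, 1.0, 0.95, 0.75, 0.85, 0.55)


def default_benchmark_spec(psnr: float | None = 25.0, seed: int = 0,
                           peak_intensity: float = 100.0) -> PhantomSpec:
    """The shipped benchmark scene: curves + straight lines, 256x256 px."""
    return PhantomSpec(
        image_shape=BENCHMARK_SHAPE,
        filaments=list(BENCHMARK_FILAMENTS),
        intensities=list(BENCHMARK_INTENSITIES),
        psnr=psnr,
        seed=seed,
        peak_intensity=peak_intensity,
    )


def default_benchmark_scene(psnr: float | None = 25.0, seed: int = 0) -> PhantomScene:
    return make_phantom(default_benchmark_spec(psnr=psnr, seed=seed))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_scene(scene: PhantomScene, outdir: str | Path) -> None:
    """Write clean/noisy TIFFs, truth-path CSV and a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "clean.tif", scene.clean_image.astype(np.float32))
    tifffile.imwrite(outdir / "noisy.tif", scene.noisy_image.astype(np.float32))
    rows = []
    for fid, pts in enumerate(scene.truth_paths):
        for i, (r, c) in enumerate(pts):
            rows.append((fid, i, r, c))
    pd.DataFrame(rows, columns=["filament_id", "point_index", "row", "col"]).to_csv(
        outdir / "truth_paths.csv", index=False)
    summary = {
        "image_shape": list(scene.spec.image_shape),
        "pixel_size_nm": scene.spec.pixel_size,
        "psf_sigma_nm": scene.spec.psf_sigma,
        "peak_intensity": scene.spec.peak_intensity,
        "n_filaments": len(scene.truth_paths),
        "requested_psnr_db": scene.spec.psnr,
        "achieved_psnr_db": None if math.isinf(scene.achieved_psnr)
        else scene.achieved_psnr,
        "seed": scene.spec.seed,
    }
    (outdir / "scene.json").write_text(json.dumps(summary, indent=2))
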