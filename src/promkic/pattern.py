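"""2D promoter patterns: point cloud, center of weight, raster images.

A promoter pattern is the cloud of (CG_SW, Kappa IC) points collected
from every sliding window of one promoter segment, plotted with GC% on
the x-axis and Kappa IC on the y-axis.  Its center of weight (the
arithmetic mean point) summarises the promoter with a single dot and is
what species-level distribution maps plot.  For classification the
cloud is rasterized onto a fixed [0,100]x[0,100] coordinate frame so
that patterns from different promoters are pixel-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .kic import WindowMeasurement, profile
from .seqio import PromoterSequence, SlidingWindowConfig

#: Default raster geometry; 348 * 268 = 93,264 pixels, the input retina
#: of the default classifier.
DEFAULT_WIDTH = 348
DEFAULT_HEIGHT = 268


@dataclass(frozen=True)
class PromoterPattern:
    sequence_id: str
    points: tuple[WindowMeasurement, ...]
    center: tuple[float, float]
    config: SlidingWindowConfig


@dataclass(frozen=True)
class PatternRaster:
    """A pattern burned onto a fixed pixel grid.

    ``intensity`` has shape (height, width); in count mode each point
    increments its pixel, in binarized mode the pixel is set to 1.
    Row 0 is the top of the image (high Kappa IC).
    """

    intensity: np.ndarray
    binarized: bool

    @property
    def width(self) -> int:
        return self.intensity.shape[1]

    @property
    def height(self) -> int:
        return self.intensity.shape[0]

    def flatten(self) -> np.ndarray:
        return self.intensity.ravel().astype(float)


def center_of_weight(points: list[tuple[float, float]]) -> tuple[float, float]:
    """Arithmetic mean point of a pattern's (CG%, KIC) cloud."""
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        raise ValueError("center of weight of an empty point set is undefined")
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def build_pattern(
    seq: PromoterSequence | str,
    cfg: SlidingWindowConfig | None = None,
    sequence_id: str | None = None,
) -> PromoterPattern:
    """Profile a sequence and package the points with their mean point."""
    cfg = cfg or SlidingWindowConfig()
    if sequence_id is None:
        sequence_id = seq.id if isinstance(seq, PromoterSequence) else "anonymous"
    points = tuple(profile(seq, cfg))
    center = center_of_weight([(p.cg_value, p.kic_value) for p in points])
    return PromoterPattern(sequence_id, points, center, cfg)


def rasterize(
    p: PromoterPattern,
    width: int = DEFAULT_WIDTH,
    height: int = DEFAULT_HEIGHT,
    binarize: bool = True,
) -> PatternRaster:
    """Map each (x, y) point to a pixel on the [0,100]^2 frame.

    x maps left-to-right, y is inverted so high Kappa IC sits at the
    top: pixel = (floor(x/100*(width-1)), floor((1 - y/100)*(height-1))).
    """
    if width < 8 or height < 8:
        raise ValueError("raster must be at least 8x8 pixels")
    xs = np.array([pt.cg_value for pt in p.points])
    ys = np.array([pt.kic_value for pt in p.points])
    if ((xs < 0) | (xs > 100) | (ys < 0) | (ys > 100)).any():
        raise ValueError("pattern contains points outside [0, 100]^2")
    cols = np.floor(xs / 100.0 * (width - 1)).astype(int)
    rows = np.floor((1.0 - ys / 100.0) * (height - 1)).astype(int)
    grid = np.zeros((height, width), dtype=np.int64)
    np.add.at(grid, (rows, cols), 1)
    if binarize:
        grid = (grid > 0).astype(np.int64)
    return PatternRaster(intensity=grid, binarized=binarize)


def pattern_distance(a: PatternRaster, b: PatternRaster) -> float:
    """Normalized L1 distance between binarized rasters, in [0, 1].

    Count-mode rasters are binarized first so the distance reflects
    shape, not point multiplicity; 0 iff the set pixels coincide.
    """
    if a.intensity.shape != b.intensity.shape:
        raise ValueError(
            f"raster shapes differ: {a.intensity.shape} vs {b.intensity.shape}"
        )
    abin = a.intensity > 0
    bbin = b.intensity > 0
    return float(np.abs(abin.astype(int) - bbin.astype(int)).sum()) / abin.size


def save_image(raster: PatternRaster, path: str | Path) -> None:
    """Write the raster as a grayscale image (PNG or BMP by extension).

    Set pixels are dark on a white background, matching how pattern
    plots read: denser pixels darker.
    """
    from PIL import Image

    grid = raster.intensity.astype(float)
    peak = grid.max() if grid.max() > 0 else 1.0
    img = (255 * (1.0 - grid / peak)).astype(np.uint8)
    Image.fromarray(img, mode="L").save(str(path))


def save_pattern_tsv(p: PromoterPattern, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("window_start\tcg_value\tkic_value\n")
        for pt in p.points:
            fh.write(f"{pt.window_start}\t{pt.cg_value:.6g}\t{pt.kic_value:.2f}\n")
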