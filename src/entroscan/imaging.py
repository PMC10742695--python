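"""Sliding-window entropy parametric imaging.

A gating window (1 pulse length × 1 pulse length by default) slides across
the envelope frame with a high overlap ratio (90% × 90%), one entropy
estimate per window position forms the entropy map, and the map is then
bilinearly interpolated back to the RF-frame grid, scan-converted to display
geometry, and color-mapped.

The parallelization contract: the map is a pure function of the window grid —
any chunking of the grid across workers returns results bit-identical to the
serial sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .entropy import (
    HIST_UNITS,
    KDE_UNITS,
    HistogramConfig,
    KDEConfig,
    entropy_hist,
    entropy_kde_windows,
)
from .errors import ConfigurationError, EntroscanError
from .io import AcquisitionMeta, EnvelopeFrame

__all__ = [
    "WindowSpec",
    "WindowGrid",
    "EntropyMap",
    "ROIStats",
    "window_grid",
    "grid_from_samples",
    "compute_entropy_map",
    "interpolate_map",
    "scan_convert",
    "roi_stats",
    "colorize",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class WindowSpec:
    """Gating-window geometry: size in mm and fractional overlap per axis.

    Defaults are 1 PL × 1 PL = 2.3 mm × 2.3 mm with 90% × 90% overlap
    (lateral × axial).
    """

    lateral_mm: float = 2.3
    axial_mm: float = 2.3
    lateral_overlap: float = 0.90
    axial_overlap: float = 0.90

    def __post_init__(self) -> None:
        if self.lateral_mm <= 0 or self.axial_mm <= 0:
            raise ConfigurationError("window size must be > 0 in both axes")
        for ov in (self.lateral_overlap, self.axial_overlap):
            if not 0.0 <= ov < 1.0:
                raise ConfigurationError("overlap fractions must lie in [0, 1)")


@dataclass(frozen=True)
class WindowGrid:
    """Window start indices, size in samples, and window-center coordinates
    (float, RF index space) along each axis."""

    axial_starts: np.ndarray
    lateral_starts: np.ndarray
    window_samples: tuple[int, int]  # (axial, lateral)
    frame_shape: tuple[int, int]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.axial_starts), len(self.lateral_starts))

    @property
    def axial_centers(self) -> np.ndarray:
        return self.axial_starts + (self.window_samples[0] - 1) / 2.0

    @property
    def lateral_centers(self) -> np.ndarray:
        return self.lateral_starts + (self.window_samples[1] - 1) / 2.0


@dataclass(frozen=True)
class EntropyMap:
    """Per-window entropy estimates on the window grid."""

    values: np.ndarray
    grid: WindowGrid
    estimator: str  # "hist" | "kde"
    units: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ROIStats:
    mean: float
    emax: float
    emin: float
    dynamic_range: float


def grid_from_samples(
    frame_shape: tuple[int, int],
    window_samples: tuple[int, int],
    overlap: tuple[float, float] = (0.90, 0.90),
) -> WindowGrid:
    """Build the window grid from a window size already expressed in samples.

    Windows start at index 0 and advance by ``stride = max(1,
    round(window * (1 - overlap)))`` per axis; positions that would overrun
    the frame edge are dropped (no partial windows).  ``overlap`` is
    (axial, lateral).
    """
    wa, wl = window_samples
    na, nl = frame_shape
    if wa < 2 or wl < 2:
        raise ConfigurationError("window must span at least 2 x 2 samples")
    if wa > na or wl > nl:
        raise EntroscanError("window exceeds frame")
    sa = max(1, _round_half_up(wa * (1.0 - overlap[0])))
    sl = max(1, _round_half_up(wl * (1.0 - overlap[1])))
    axial_starts = np.arange(0, na - wa + 1, sa)
    lateral_starts = np.arange(0, nl - wl + 1, sl)
    return WindowGrid(
        axial_starts=axial_starts,
        lateral_starts=lateral_starts,
        window_samples=(wa, wl),
        frame_shape=(na, nl),
    )


def window_grid(
    frame_shape: tuple[int, int], meta: AcquisitionMeta, spec: WindowSpec = WindowSpec()
) -> WindowGrid:
    """Convert a physical window spec to samples and build the grid.

    Axial size uses the depth-per-sample of the acquisition; lateral size uses
    the scanline pitch at the transducer face (round-half-up in both axes;
    beam divergence with depth is ignored for window sizing).
    """
    wa = _round_half_up(spec.axial_mm / meta.depth_per_sample_mm)
    wl = _round_half_up(spec.lateral_mm / meta.lateral_pitch_mm())
    wa, wl = max(wa, 2), max(wl, 2)
    return grid_from_samples(
        frame_shape, (wa, wl), overlap=(spec.axial_overlap, spec.lateral_overlap)
    )


def _gather_windows(amp: np.ndarray, grid: WindowGrid, rows: np.ndarray) -> np.ndarray:
    """Flattened window samples (len(rows)*n_lateral, wa*wl) for grid rows."""
    wa, wl = grid.window_samples
    view = sliding_window_view(amp, (wa, wl))
    blk = view[np.ix_(grid.axial_starts[rows], grid.lateral_starts)]
    return blk.reshape(-1, wa * wl)


def compute_entropy_map(
    env: EnvelopeFrame,
    spec: WindowSpec = WindowSpec(),
    estimator: str = "kde",
    hist_cfg: HistogramConfig = HistogramConfig(),
    kde_cfg: KDEConfig = KDEConfig(),
    workers: int = 1,
) -> EntropyMap:
    """Compute the per-window entropy map of an envelope frame.

    Entropy is estimated on the uncompressed envelope amplitudes (B-mode log
    compression is display-only).  ``workers`` chunks grid rows across a
    thread pool; the result is bit-identical for any worker count.  Windows
    with zero spread yield the estimator's degenerate value (0 bits for the
    histogram, NaN for the KDE) instead of aborting the frame.
    """
    if estimator not in ("hist", "kde"):
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    grid = window_grid(env.shape, env.meta, spec)
    n_ax, n_lat = grid.shape
    amp = env.amplitude

    def _rows_entropy(rows: np.ndarray) -> np.ndarray:
        wins = _gather_windows(amp, grid, rows)
        if estimator == "kde":
            vals = entropy_kde_windows(wins, kde_cfg)
        else:
            vals = np.array([entropy_hist(w, hist_cfg) for w in wins])
        return vals.reshape(len(rows), n_lat)

    row_idx = np.arange(n_ax)
    if workers <= 1:
        values = _rows_entropy(row_idx)
    else:
        chunks = np.array_split(row_idx, min(workers, n_ax))
        parts = Parallel(n_jobs=workers, prefer="threads")(
            delayed(_rows_entropy)(c) for c in chunks if len(c)
        )
        values = np.vstack(parts)
    units = KDE_UNITS if estimator == "kde" else HIST_UNITS
    return EntropyMap(values=values, grid=grid, estimator=estimator, units=units)


def interpolate_map(emap: EntropyMap, target_shape: tuple[int, int]) -> np.ndarray:
    """Bilinearly interpolate the entropy map to the full RF-frame grid.

    Window-center values are preserved exactly; pixels beyond the outermost
    window centers are edge-replicated, so the output never leaves
    [map min, map max].
    """
    if emap.shape[0] < 2 or emap.shape[1] < 2:
        raise EntroscanError("entropy map must be at least 2 x 2 to interpolate")
    grid = emap.grid
    interp = RegularGridInterpolator(
        (grid.axial_centers, grid.lateral_centers), emap.values, method="linear"
    )
    rows = np.clip(np.arange(target_shape[0]), grid.axial_centers[0], grid.axial_centers[-1])
    cols = np.clip(np.arange(target_shape[1]), grid.lateral_centers[0], grid.lateral_centers[-1])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return interp(np.stack([rr, cc], axis=-1))


def scan_convert(
    image: np.ndarray, meta: AcquisitionMeta, fill: float = np.nan
) -> np.ndarray:
    """Resample an acquisition-coordinate image to display geometry.

    Linear arrays: identity along the axial axis, lateral axis resampled so
    display pixels are square (pixel pitch = depth per sample).  Convex
    arrays: polar-to-Cartesian resampling about the virtual apex using the
    probe radius and sector angle; pixels outside the sector are set to
    ``fill`` (NaN by default, i.e. transparent in the color mapping).
    """
    img = np.asarray(image, dtype=np.float64)
    n_ax, n_lat = img.shape
    dps = meta.depth_per_sample_mm
    if meta.geometry == "linear":
        width_mm = (n_lat - 1) * meta.scanline_pitch
        n_out = max(2, _round_half_up(width_mm / dps) + 1)
        xs_mm = np.linspace(0.0, width_mm, n_out)
        cols = xs_mm / meta.scanline_pitch
        rows = np.arange(n_ax, dtype=np.float64)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return ndimage.map_coordinates(
            img, [rr, cc], order=1, mode="nearest"
        )
    if meta.convex_radius is None or meta.sector_angle is None:
        raise ConfigurationError("convex geometry requires convex_radius and sector_angle")
    radius = float(meta.convex_radius)
    half = np.deg2rad(meta.sector_angle) / 2.0
    dtheta = np.deg2rad(meta.sector_angle) / (n_lat - 1)
    r_max = radius + (n_ax - 1) * dps
    x_max = r_max * np.sin(half)
    z_min = radius * np.cos(half)
    xs = np.arange(-x_max, x_max + dps / 2, dps)
    zs = np.arange(z_min, r_max + dps / 2, dps)
    xx, zz = np.meshgrid(xs, zs, indexing="xy")
    r = np.hypot(xx, zz)
    theta = np.arctan2(xx, zz)
    ri = (r - radius) / dps
    ci = (theta + half) / dtheta
    out = ndimage.map_coordinates(
        img, [ri, ci], order=1, mode="constant", cval=fill
    )
    outside = (r < radius) | (r > r_max) | (np.abs(theta) > half)
    out[outside] = fill
    return out


def roi_stats(value_image: np.ndarray, roi_mask: np.ndarray) -> ROIStats:
    """Mean, max, min and dynamic range DR = Emax − Emin over the ROI.

    Only finite (non-sentinel) pixels inside the mask contribute.
    """
    img = np.asarray(value_image, dtype=np.float64)
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != img.shape:
        raise EntroscanError("ROI mask shape must match the image")
    sel = mask & np.isfinite(img)
    if not np.any(sel):
        raise EntroscanError("ROI outside image")
    vals = img[sel]
    emax, emin = float(np.max(vals)), float(np.min(vals))
    return ROIStats(
        mean=float(np.mean(vals)), emax=emax, emin=emin, dynamic_range=emax - emin
    )


def colorize(
    value_image: np.ndarray,
    vmin: float | None = None,
    vmax: float | None = None,
    cmap: str = "viridis",
) -> np.ndarray:
    """Map a value image to RGBA uint8 (NaN sentinels become transparent).

    Per-image [min, max] scaling by default; pass ``vmin``/``vmax`` for a
    fixed range comparable across subjects.
    """
    import matplotlib

    img = np.asarray(value_image, dtype=np.float64)
    finite = np.isfinite(img)
    if not np.any(finite):
        raise EntroscanError("no finite values to color-map")
    lo = float(np.nanmin(img)) if vmin is None else vmin
    hi = float(np.nanmax(img)) if vmax is None else vmax
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((img - lo) / span, 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](np.nan_to_num(norm, nan=0.0), bytes=True).copy()
    rgba[~finite, 3] = 0
    return rgba
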