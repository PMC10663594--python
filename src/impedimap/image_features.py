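"""Well-level morphology features from parameter-map movies.

The map stack of a well is treated like a time-lapse image: a reference scan
taken in cell-free media calibrates a per-pixel detection threshold, the
resulting cell mask yields confluence and masked medians, and frame-to-frame
differences yield a normalized RMS motility statistic.  Local circular
depressions in the attachment map (lateral field, 16 kHz) are detected as
doming events — transient lift-off of the cell sheet driven by
transepithelial water transport, appearing as discs of roughly 150 um
diameter (4-10 px at 25 um pitch).

Sentinel convention: statistics that are undefined for a well/scan (e.g. the
masked median of an empty mask) are recorded as NaN rather than raising, so
plate tables stay rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .plate_model import (
    ElectrodeArray,
    ParameterMapStack,
    WellTimeSeries,
)

__all__ = [
    "FeatureConfig",
    "CalibrationError",
    "compute_epoxy_mask",
    "compute_cell_mask",
    "confluence",
    "masked_median",
    "normalized_rms",
    "rms_pixel_map",
    "detect_domes",
    "barrier_resistance_area",
    "extract_timeseries",
]

#: Map used for cell masking and RMS; the VF 4 kHz magnitude gives the best
#: cell/no-cell contrast.
DEFAULT_MASK_SOURCE = ("VF", "mag@4000")
DEFAULT_ATTACHMENT_SOURCE = ("LF", "mag@16000")


class CalibrationError(ValueError):
    """Raised when the reference measurement is missing or unusable."""


@dataclass
class FeatureConfig:
    """Tunable settings of the feature-extraction stage.

    threshold_rel
        Cell detection threshold as a fraction above the per-pixel reference
        impedance; a pixel is cell-covered when its value exceeds
        ``reference * (1 + threshold_rel)``.
    epoxy_threshold_rel
        Relative deviation from the reference-map median beyond which a pixel
        is flagged as occluded by spillover epoxy.
    rms_frame_lag
        Number of scans between the two frames differenced for the RMS
        motility statistic (1 = consecutive 15-min scans).  A second,
        longer-lag RMS trace (``rms_long_frame_lag``, default 4 scans = 1 h)
        captures slower migratory movement.
    dome_depth_rel
        Fractional attachment decrease below the cell-masked median that
        counts as locally depressed.
    """

    mask_source: tuple[str, str] = DEFAULT_MASK_SOURCE
    threshold_rel: float = 0.2
    epoxy_threshold_rel: float = 0.5
    rms_source: tuple[str, str] = DEFAULT_MASK_SOURCE
    rms_frame_lag: int = 1
    rms_long_frame_lag: int = 4
    attachment_source: tuple[str, str] = DEFAULT_ATTACHMENT_SOURCE
    dome_min_diameter_px: float = 4.0
    dome_max_diameter_px: float = 10.0
    dome_depth_rel: float = 0.25
    dome_median_filter_px: int = 3

    def __post_init__(self) -> None:
        if self.threshold_rel <= 0:
            raise ValueError("threshold_rel must be positive")
        if self.rms_frame_lag < 1:
            raise ValueError("rms_frame_lag must be >= 1")


def compute_epoxy_mask(
    reference_stack: ParameterMapStack | np.ndarray,
    cfg: FeatureConfig | None = None,
) -> np.ndarray:
    """Flag electrodes occluded by spillover epoxy from the reference scan.

    Epoxy pixels deviate strongly from the plate-wide default impedance in
    solution; a pixel is flagged when its reference value departs from the
    reference-map median by more than ``epoxy_threshold_rel`` (relative).
    """
    cfg = cfg or FeatureConfig()
    if reference_stack is None:
        raise CalibrationError("no reference measurement available")
    ref = (
        reference_stack[cfg.mask_source]
        if isinstance(reference_stack, ParameterMapStack)
        else np.asarray(reference_stack, dtype=float)
    )
    med = float(np.median(ref))
    if med <= 0:
        raise CalibrationError("non-positive reference median; bad calibration scan")
    return np.abs(ref - med) > cfg.epoxy_threshold_rel * med


def compute_cell_mask(
    stack: ParameterMapStack | np.ndarray,
    reference: ParameterMapStack | np.ndarray,
    cfg: FeatureConfig | None = None,
    epoxy_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold a map against its cell-free reference to locate cells.

    A pixel belongs to the cell mask iff its value exceeds the per-pixel
    reference by more than ``threshold_rel`` (relative) and it is not epoxy.
    """
    cfg = cfg or FeatureConfig()
    cur = (
        stack[cfg.mask_source]
        if isinstance(stack, ParameterMapStack)
        else np.asarray(stack, dtype=float)
    )
    ref = (
        reference[cfg.mask_source]
        if isinstance(reference, ParameterMapStack)
        else np.asarray(reference, dtype=float)
    )
    if cur.shape != ref.shape:
        raise ValueError("stack and reference shapes differ")
    if epoxy_mask is None:
        epoxy_mask = compute_epoxy_mask(reference, cfg)
    bad = (ref <= 0) & ~epoxy_mask
    if np.any(bad):
        coords = np.argwhere(bad)[:5].tolist()
        raise CalibrationError(f"non-positive reference pixels at {coords}")
    mask = cur > ref * (1.0 + cfg.threshold_rel)
    return mask & ~epoxy_mask


def confluence(cell_mask: np.ndarray, epoxy_mask: np.ndarray | None = None) -> float:
    """Percentage of non-epoxy electrodes occupied by cells, in [0, 100]."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if epoxy_mask is None:
        epoxy_mask = np.zeros_like(cell_mask)
    epoxy_mask = np.asarray(epoxy_mask, dtype=bool)
    if cell_mask.shape != epoxy_mask.shape:
        raise ValueError("mask shapes differ")
    denom = int((~epoxy_mask).sum())
    if denom == 0:
        raise ValueError("all pixels are epoxy; confluence undefined")
    return 100.0 * int((cell_mask & ~epoxy_mask).sum()) / denom


def masked_median(map_: np.ndarray, cell_mask: np.ndarray) -> float:
    """Median of the map over cell-covered pixels; NaN sentinel if the mask is empty."""
    map_ = np.asarray(map_, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if map_.shape != cell_mask.shape:
        raise ValueError("map and mask shapes differ")
    if not cell_mask.any():
        return float("nan")
    return float(np.median(map_[cell_mask]))


def normalized_rms(
    frame_t: np.ndarray,
    frame_prev: np.ndarray,
    epoxy_mask: np.ndarray | None,
    cell_median: float,
) -> float:
    """RMS of the frame difference over non-epoxy pixels, divided by the
    cell-masked median (normalizes out overall magnitude changes)."""
    frame_t = np.asarray(frame_t, dtype=float)
    frame_prev = np.asarray(frame_prev, dtype=float)
    if frame_t.shape != frame_prev.shape:
        raise ValueError("frame shapes differ")
    if not np.isfinite(cell_median) or cell_median <= 0:
        raise ValueError("cell median must be positive for RMS normalization")
    keep = (
        np.ones(frame_t.shape, dtype=bool)
        if epoxy_mask is None
        else ~np.asarray(epoxy_mask, dtype=bool)
    )
    diff = frame_t[keep] - frame_prev[keep]
    return float(np.sqrt(np.mean(diff**2)) / cell_median)


def rms_pixel_map(
    frame_t: np.ndarray,
    frame_prev: np.ndarray,
    epoxy_mask: np.ndarray | None,
    cell_median: float,
) -> np.ndarray:
    """Per-pixel normalized frame difference magnitude (epoxy pixels NaN).

    Pooling these pixel values across wells gives the population
    distributions used for heterogeneity scoring.
    """
    if not np.isfinite(cell_median) or cell_median <= 0:
        raise ValueError("cell median must be positive for RMS normalization")
    out = np.abs(np.asarray(frame_t, float) - np.asarray(frame_prev, float)) / cell_median
    if epoxy_mask is not None:
        out = out.copy()
        out[np.asarray(epoxy_mask, dtype=bool)] = np.nan
    return out


def detect_domes(
    attachment_map: np.ndarray,
    cell_mask: np.ndarray,
    cfg: FeatureConfig | None = None,
) -> list[dict]:
    """Detect doming events as circular local depressions of attachment.

    The attachment map is median-filtered, compared against the cell-masked
    median level, and connected depressed regions whose equivalent diameter
    falls in the configured size gate are reported with their centroid.
    Returns a (possibly empty) list of ``{"center": (row, col),
    "diameter_px": float}`` records.
    """
    cfg = cfg or FeatureConfig()
    attachment_map = np.asarray(attachment_map, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        return []
    smooth = ndimage.median_filter(attachment_map, size=cfg.dome_median_filter_px)
    level = np.median(smooth[cell_mask])
    if level <= 0:
        return []
    depressed = (smooth < level * (1.0 - cfg.dome_depth_rel)) & cell_mask
    labels, n = ndimage.label(depressed)
    out = []
    for i in range(1, n + 1):
        region = labels == i
        area = int(region.sum())
        diam = 2.0 * np.sqrt(area / np.pi)
        if cfg.dome_min_diameter_px <= diam <= cfg.dome_max_diameter_px:
            r, c = ndimage.center_of_mass(region)
            out.append({"center": (float(r), float(c)), "diameter_px": float(diam)})
    return out


def barrier_resistance_area(
    impedance_ohm: float | np.ndarray, electrode_area_cm2: float | None = None
) -> float | np.ndarray:
    """Convert an electrode impedance magnitude to a TEER-equivalent
    resistance-area product (Ohm * cm^2), using the effective unit area of one
    electrode (25 x 25 um^2 = 6.25e-6 cm^2) by default."""
    if electrode_area_cm2 is None:
        electrode_area_cm2 = ElectrodeArray().electrode_area_cm2
    z = np.asarray(impedance_ohm, dtype=float)
    if np.any(z <= 0) or electrode_area_cm2 <= 0:
        raise ValueError("impedance and electrode area must be positive")
    out = z * electrode_area_cm2
    return float(out) if np.ndim(impedance_ohm) == 0 else out


def extract_timeseries(
    scans: list[ParameterMapStack],
    reference: ParameterMapStack,
    cfg: FeatureConfig | None = None,
    params: list[tuple[str, str]] | None = None,
) -> WellTimeSeries:
    """Reduce one well's scan sequence to scalar traces.

    Produces, per scan: the confluence of the thresholded cell mask, the
    masked median of each requested map, and (lagged) the normalized RMS of
    the configured motility source.  The RMS trace is ``lag`` scans shorter
    than the others and end-aligned on the time axis.
    """
    cfg = cfg or FeatureConfig()
    if not scans:
        raise ValueError("no scans supplied")
    times = np.array([s.scan_time_h for s in scans], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("scans must be strictly time-ordered")
    if params is None:
        params = [
            ("VF", "mag@250"),
            ("VF", "mag@1000"),
            ("VF", "mag@4000"),
            ("VF", "mag@16000"),
            ("LF", "mag@16000"),
        ]
    epoxy = compute_epoxy_mask(reference, cfg)
    well_id = scans[0].well_id

    conf = np.empty(len(scans))
    medians = {p: np.empty(len(scans)) for p in params}
    rms_frames = []
    cell_medians = np.empty(len(scans))
    for i, stack in enumerate(scans):
        mask = compute_cell_mask(stack, reference, cfg, epoxy_mask=epoxy)
        conf[i] = confluence(mask, epoxy)
        for p in params:
            medians[p][i] = masked_median(stack[p], mask)
        rms_frames.append(stack[cfg.rms_source])
        cell_medians[i] = masked_median(stack[cfg.rms_source], mask)

    def _rms_trace(lag: int) -> np.ndarray:
        trace = np.full(max(len(scans) - lag, 0), np.nan)
        for i in range(lag, len(scans)):
            cm = cell_medians[i]
            if np.isfinite(cm) and cm > 0:
                trace[i - lag] = normalized_rms(
                    rms_frames[i], rms_frames[i - lag], epoxy, cm
                )
        return trace

    values: dict[str, np.ndarray] = {"confluence": conf}
    for p in params:
        values[f"{p[0]}:{p[1]}"] = medians[p]
    values["rms"] = _rms_trace(cfg.rms_frame_lag)
    values["rms_long"] = _rms_trace(cfg.rms_long_frame_lag)
    return WellTimeSeries(well_id=well_id, times_h=times, values=values)
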