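"""Pupil diameter from grayscale frames by pixel-area counting.

The pupil boundary is detected automatically: the frame is thresholded,
pixels below the cut form candidate regions, the largest dark connected
component (8-connectivity) is taken as the pupil, and holes left by
specular highlights are filled before counting.  The area in pixels yields
the equivalent diameter ``2 * sqrt(area / pi)``, which the pinhole camera
model converts to millimetres using the measured camera distance.

The default threshold is a three-class multi-Otsu with the lowest cut
taken: the scene has three intensity populations (pupil, iris, sclera) and
a plain two-class Otsu tends to split iris from sclera, merging the pupil
into the iris.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label, regionprops

from .protocol import ProtocolTimeline
from .render import EyeFrame
from .trace import QUALITY_MISSING, QUALITY_OK, PupilTrace, illumination_labels


class SegmentationError(ValueError):
    """Raised for invalid frames or parameters."""


@dataclass(frozen=True)
class SegmentationResult:
    """Pupil measurement of one frame.

    ``confidence`` is the fraction of region boundary pixels whose distance
    to the centroid is consistent with a circle of the equivalent radius.
    An explicit "no pupil" result has ``area_px == 0``.
    """

    area_px: int
    equivalent_diameter_px: float
    compensated_diameter_mm: float
    center_px: tuple[float, float]  # (row, col)
    confidence: float

    @property
    def found(self) -> bool:
        return self.area_px > 0


_NO_PUPIL = SegmentationResult(0, 0.0, 0.0, (float("nan"), float("nan")), 0.0)


def compensate_distance(
    equivalent_diameter_px: float,
    camera_distance_mm: float,
    pixel_pitch_mm: float,
    focal_length_mm: float,
) -> float:
    """Pixel diameter to millimetres via the pinhole model.

    diameter_mm = diameter_px * pixel_pitch * camera_distance / focal_length
    """
    if camera_distance_mm <= 0 or pixel_pitch_mm <= 0 or focal_length_mm <= 0:
        raise SegmentationError("camera distance, pitch and focal length must be positive")
    if equivalent_diameter_px < 0:
        raise SegmentationError("equivalent_diameter_px must be >= 0")
    return equivalent_diameter_px * pixel_pitch_mm * camera_distance_mm / focal_length_mm


def _circle_confidence(mask: np.ndarray, centroid: tuple[float, float], radius: float) -> float:
    boundary = mask & ~ndimage.binary_erosion(mask)
    rr, cc = np.nonzero(boundary)
    if len(rr) == 0:
        return 0.0
    dist = np.hypot(rr - centroid[0], cc - centroid[1])
    tol = max(1.5, 0.1 * radius)
    return float(np.mean(np.abs(dist - radius) <= tol))


def segment_pupil(
    frame: EyeFrame,
    threshold_mode: str = "otsu",
    fixed_threshold: float | None = None,
) -> SegmentationResult:
    """Segment the pupil of one frame.

    ``threshold_mode="otsu"`` uses a 3-class multi-Otsu (lowest cut);
    ``"fixed"`` uses ``fixed_threshold``.  Ties between equal-size dark
    regions break deterministically toward the topmost-leftmost centroid.
    Returns the explicit "no pupil" result when nothing lies below the
    threshold.
    """
    img = np.asarray(frame.pixels)
    if img.size == 0:
        raise SegmentationError("empty frame")
    if threshold_mode == "otsu":
        if np.ptp(img) == 0:
            return _NO_PUPIL  # uniform frame: nothing darker than anything
        try:
            thr = float(threshold_multiotsu(img, classes=3)[0])
        except ValueError:  # fewer than 3 grey levels present
            thr = float(threshold_otsu(img))
    elif threshold_mode == "fixed":
        if fixed_threshold is None:
            raise SegmentationError("fixed threshold_mode needs fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise SegmentationError(f"unknown threshold_mode {threshold_mode!r}")

    dark = img < thr
    if not dark.any():
        return _NO_PUPIL
    labels = label(dark, connectivity=2)
    props = regionprops(labels)
    # largest region; ties -> topmost then leftmost centroid
    props.sort(key=lambda p: (-p.area, p.centroid[0], p.centroid[1]))
    region = props[0]
    mask = ndimage.binary_fill_holes(labels == region.label)
    area = int(mask.sum())
    eq_d_px = 2.0 * np.sqrt(area / np.pi)
    centroid = ndimage.center_of_mass(mask)
    return SegmentationResult(
        area_px=area,
        equivalent_diameter_px=float(eq_d_px),
        compensated_diameter_mm=compensate_distance(
            float(eq_d_px),
            frame.camera_distance_mm,
            frame.pixel_pitch_mm,
            frame.focal_length_mm,
        ),
        center_px=(float(centroid[0]), float(centroid[1])),
        confidence=_circle_confidence(mask, centroid, eq_d_px / 2.0),
    )


def frames_to_trace(
    frame_pairs,
    timeline: ProtocolTimeline,
    sample_rate_hz: float | None = None,
    threshold_mode: str = "otsu",
) -> PupilTrace:
    """Assemble (time_s, right EyeFrame, left EyeFrame) triples into a trace.

    Timestamps must be strictly increasing and lie within the session.
    Frames where no pupil is found are flagged ``missing``.
    """
    frame_pairs = list(frame_pairs)
    if not frame_pairs:
        raise SegmentationError("empty frame sequence")
    times = np.array([t for t, _, _ in frame_pairs], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise SegmentationError("frame timestamps must be strictly increasing")
    if times[0] < 0 or times[-1] >= timeline.total_s:
        raise SegmentationError("frame timestamps must lie within the session")
    if sample_rate_hz is None:
        sample_rate_hz = (
            (len(times) - 1) / (times[-1] - times[0]) if len(times) > 1 else 1.0
        )

    right = np.full(len(times), np.nan)
    left = np.full(len(times), np.nan)
    quality = np.array([QUALITY_OK] * len(times), dtype=object)
    for i, (_, fr, fl) in enumerate(frame_pairs):
        rr = segment_pupil(fr, threshold_mode=threshold_mode)
        ll = segment_pupil(fl, threshold_mode=threshold_mode)
        if rr.found and ll.found:
            right[i] = rr.compensated_diameter_mm
            left[i] = ll.compensated_diameter_mm
        else:
            quality[i] = QUALITY_MISSING
    return PupilTrace(
        sample_rate_hz=float(sample_rate_hz),
        time_s=times,
        right_mm=right,
        left_mm=left,
        illumination=illumination_labels(timeline, times),
        quality=quality,
    )
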