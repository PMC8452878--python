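"""Synthetic infrared eye frames with known pupil geometry.

Frames emulate what the pupillometer camera sees: a dark pupil disc inside
a brighter iris annulus on a bright scleral background, optionally with a
specular highlight inside the pupil.  The projection follows the pinhole
model: a feature of physical size ``x`` mm at camera distance ``D`` mm
spans ``x * focal_length / (pixel_pitch * D)`` pixels.  Edges are rendered
with analytic anti-aliasing (1-px linear coverage ramp) so pixel-area
counting recovers the disc area accurately; the renderer's own >=50%
coverage mask is the ground-truth pupil mask.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

#: Default camera model: 12-mm focal length, 5-um pixel pitch.  At 60 mm an
#: 80-px feature corresponds to 2.0 mm.
DEFAULT_FOCAL_LENGTH_MM = 12.0
DEFAULT_PIXEL_PITCH_MM = 0.005

#: Rendered grey levels (8-bit): pupil < iris < sclera, highlight brightest.
PUPIL_LEVEL = 25
IRIS_LEVEL = 110
SCLERA_LEVEL = 205
HIGHLIGHT_LEVEL = 250

#: Smallest resolvable projected pupil, px.
MIN_PUPIL_PX = 4.0


class RenderError(ValueError):
    """Raised for geometries the camera model cannot render."""


@dataclass(frozen=True)
class PupilGeometry:
    """Physical truth of one rendered eye.

    ``iris_diameter_mm`` defaults to 2.4x the pupil so the annulus always
    encloses the disc; ``highlight_frac`` is the specular highlight's
    diameter as a fraction of the pupil diameter (0 = none).
    """

    pupil_diameter_mm: float
    iris_diameter_mm: float | None = None
    highlight_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.pupil_diameter_mm <= 0:
            raise RenderError("pupil_diameter_mm must be positive")
        iris = self.iris_diameter_mm
        if iris is None:
            object.__setattr__(self, "iris_diameter_mm", 2.4 * self.pupil_diameter_mm)
        elif iris <= self.pupil_diameter_mm:
            raise RenderError("iris must be larger than the pupil")
        if not 0.0 <= self.highlight_frac < 0.5:
            raise RenderError("highlight_frac must be in [0, 0.5)")


@dataclass
class EyeFrame:
    """One grayscale frame plus camera metadata and rendering truth."""

    pixels: np.ndarray  # uint8, row-major, origin top-left
    pixel_pitch_mm: float
    camera_distance_mm: float
    focal_length_mm: float
    truth_pupil_center_px: tuple[float, float]  # (row, col)
    truth_pupil_diameter_mm: float
    truth_mask: np.ndarray | None = None  # >=50% coverage pupil mask

    @property
    def px_per_mm(self) -> float:
        return self.focal_length_mm / (self.pixel_pitch_mm * self.camera_distance_mm)


def _disc_coverage(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    """Per-pixel disc coverage in [0, 1] with a 1-px anti-aliased edge."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    return np.clip(radius_px + 0.5 - dist, 0.0, 1.0)


def render_frame(
    truth_geometry: PupilGeometry,
    camera_distance_mm: float,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM,
    focal_length_mm: float = DEFAULT_FOCAL_LENGTH_MM,
    margin_px: int = 12,
) -> EyeFrame:
    """Render one eye frame at the given camera distance.

    The image is sized to contain the iris annulus plus a scleral margin.
    Raises RenderError when the projected pupil is smaller than 4 px
    (unresolvable) or the geometry is degenerate.
    """
    if camera_distance_mm <= 0 or pixel_pitch_mm <= 0 or focal_length_mm <= 0:
        raise RenderError("camera parameters must be positive")
    scale = focal_length_mm / (pixel_pitch_mm * camera_distance_mm)
    pupil_d_px = truth_geometry.pupil_diameter_mm * scale
    if pupil_d_px < MIN_PUPIL_PX:
        raise RenderError(
            f"projected pupil {pupil_d_px:.2f} px < {MIN_PUPIL_PX} px is unresolvable"
        )
    iris_r_px = truth_geometry.iris_diameter_mm * scale / 2.0
    size = int(np.ceil(2 * iris_r_px)) + 2 * margin_px
    center = ((size - 1) / 2.0, (size - 1) / 2.0)

    img = np.full((size, size), float(SCLERA_LEVEL))
    iris_cov = _disc_coverage((size, size), center, iris_r_px)
    img += iris_cov * (IRIS_LEVEL - SCLERA_LEVEL)
    pupil_cov = _disc_coverage((size, size), center, pupil_d_px / 2.0)
    img += pupil_cov * (PUPIL_LEVEL - IRIS_LEVEL)
    if truth_geometry.highlight_frac > 0:
        hl_r = truth_geometry.highlight_frac * pupil_d_px / 2.0
        # offset the highlight off-centre but keep it inside the pupil
        hl_center = (center[0] - pupil_d_px / 8.0, center[1] + pupil_d_px / 8.0)
        hl_cov = _disc_coverage((size, size), hl_center, hl_r)
        img += hl_cov * (HIGHLIGHT_LEVEL - PUPIL_LEVEL)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return EyeFrame(
        pixels=pixels,
        pixel_pitch_mm=pixel_pitch_mm,
        camera_distance_mm=camera_distance_mm,
        focal_length_mm=focal_length_mm,
        truth_pupil_center_px=center,
        truth_pupil_diameter_mm=truth_geometry.pupil_diameter_mm,
        truth_mask=pupil_cov >= 0.5,
    )


def write_frame(frame: EyeFrame, png_path: str | Path) -> None:
    """8-bit grayscale PNG plus a sidecar JSON of camera metadata and truth."""
    png_path = Path(png_path)
    Image.fromarray(frame.pixels, mode="L").save(png_path)
    sidecar = {
        "pixel_pitch_mm": frame.pixel_pitch_mm,
        "camera_distance_mm": frame.camera_distance_mm,
        "focal_length_mm": frame.focal_length_mm,
        "truth_pupil_center_px": list(frame.truth_pupil_center_px),
        "truth_pupil_diameter_mm": frame.truth_pupil_diameter_mm,
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_frame(png_path: str | Path) -> EyeFrame:
    png_path = Path(png_path)
    pixels = np.asarray(Image.open(png_path).convert("L"))
    meta = json.loads(png_path.with_suffix(".json").read_text())
    return EyeFrame(
        pixels=pixels,
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        camera_distance_mm=meta["camera_distance_mm"],
        focal_length_mm=meta["focal_length_mm"],
        truth_pupil_center_px=tuple(meta["truth_pupil_center_px"]),
        truth_pupil_diameter_mm=meta["truth_pupil_diameter_mm"],
    )
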