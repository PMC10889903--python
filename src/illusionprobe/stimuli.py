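"""Parametric synthesis of Skye's Oblique Grating stimuli.

The stimulus is a Café-Wall-family geometric illusion: four horizontal
coloured bars, each decorated along its long edges with small black and
white diamonds in alternating order, drawn over a background of vertical
black/blue stripes.  Depending on the alternation phase of the diamonds
(positional setting I or II) the physically horizontal bars appear tilted
clockwise or counterclockwise.

Rendering is deterministic: polygons are drawn at a supersampled
resolution and box-filtered down, so identical specs produce bit-identical
rasters and sub-degree bar rotations survive as anti-aliased subpixel
structure.
"""

from __future__ import annotations

import colorsys
import dataclasses
import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, ImageDraw

__all__ = [
    "ColorSpec",
    "CanvasSpec",
    "StimulusSpec",
    "TiltSpec",
    "RenderedImage",
    "default_color_ring",
    "enumerate_stimulus_grid",
    "render_illusion",
    "render_tilted",
    "DEFAULT_DIAMOND_WIDTHS",
    "POSITIONAL_SETTINGS",
]

#: Diamond side lengths (px) spanned by the default stimulus grid.
DEFAULT_DIAMOND_WIDTHS: tuple[int, ...] = (5, 6, 7, 8, 9, 10)

#: The two mirror arrangements of the black/white diamond alternation.
POSITIONAL_SETTINGS: tuple[str, str] = ("I", "II")

#: Supersampling factor used when rasterising polygons.
_SUPERSAMPLE = 4

#: Hue names at 30-degree steps around a fully saturated RGB colour ring.
_RING_NAMES = (
    "red",
    "orange",
    "yellow",
    "yellow-green",
    "green",
    "spring green",
    "cyan",
    "dodger blue",
    "blue",
    "violet",
    "magenta",
    "rose",
)


@dataclass(frozen=True)
class ColorSpec:
    """One hue of the 12-colour RGB ring used for the bars."""

    name: str
    rgb: tuple[int, int, int]
    ring_index: int

    def __post_init__(self) -> None:
        if not all(0 <= c <= 255 for c in self.rgb):
            raise ValueError(f"rgb channels must be in 0..255, got {self.rgb}")
        if self.ring_index < 0:
            raise ValueError("ring_index must be non-negative")


@dataclass(frozen=True)
class CanvasSpec:
    """Geometry of the rendered scene.

    The defaults reproduce a 560x160 px canvas with four evenly spaced
    horizontal bars of 14 px thickness over 10 px vertical background
    stripes alternating black and dark blue.
    """

    width_px: int = 560
    height_px: int = 160
    bar_length_px: int = 560
    bar_count: int = 4
    bar_thickness_px: int = 14
    background_stripe_width_px: int = 10
    background_colors: tuple[tuple[int, int, int], tuple[int, int, int]] = (
        (0, 0, 0),
        (0, 0, 96),
    )

    def __post_init__(self) -> None:
        if min(
            self.width_px,
            self.height_px,
            self.bar_length_px,
            self.bar_thickness_px,
            self.background_stripe_width_px,
        ) <= 0:
            raise ValueError("all canvas dimensions must be positive")
        if self.bar_count < 1:
            raise ValueError("bar_count must be >= 1")
        if self.bar_length_px > self.width_px:
            raise ValueError("bar_length_px must not exceed width_px")

    @property
    def diamond_pitch_px(self) -> int:
        """Horizontal spacing of consecutive diamonds along a bar."""
        return 2 * self.background_stripe_width_px


@dataclass(frozen=True)
class StimulusSpec:
    """One point of the illusion grid: hue x diamond width x setting."""

    color: ColorSpec
    diamond_width_px: int
    positional_setting: str
    canvas: CanvasSpec = field(default_factory=CanvasSpec)

    def __post_init__(self) -> None:
        if self.positional_setting not in POSITIONAL_SETTINGS:
            raise ValueError(
                f"positional_setting must be one of {POSITIONAL_SETTINGS}, "
                f"got {self.positional_setting!r}"
            )
        if self.diamond_width_px <= 0:
            raise ValueError("diamond_width_px must be positive")

    @property
    def stimulus_id(self) -> str:
        return (
            f"{self.color.name.replace(' ', '_')}"
            f"-w{self.diamond_width_px}-{self.positional_setting}"
        )


@dataclass(frozen=True)
class TiltSpec:
    """Signed bar angles in degrees, clockwise-positive, one per bar."""

    angles_deg: tuple[float, float, float, float]
    max_abs_deg: float = 5.0

    def __post_init__(self) -> None:
        if len(self.angles_deg) != 4:
            raise ValueError("TiltSpec requires exactly four angles")
        for a in self.angles_deg:
            if not math.isfinite(a):
                raise ValueError("tilt angles must be finite")
            if abs(a) > self.max_abs_deg:
                raise ValueError(
                    f"|angle| = {abs(a):.3f} exceeds maximum {self.max_abs_deg}"
                )

    @classmethod
    def zero(cls) -> "TiltSpec":
        return cls((0.0, 0.0, 0.0, 0.0))


@dataclass(frozen=True)
class RenderedImage:
    """An 8-bit RGB raster together with its generating parameters."""

    pixels: np.ndarray
    spec: StimulusSpec
    tilt: TiltSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be an HxWx3 uint8 array")
        if px.shape[0] != self.spec.canvas.height_px or px.shape[1] != self.spec.canvas.width_px:
            raise ValueError("raster dimensions must match the canvas spec")

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.pixels, mode="RGB")

    def sha256(self) -> str:
        return hashlib.sha256(self.pixels.tobytes()).hexdigest()

    def metadata(self) -> dict:
        meta = {
            "stimulus": {
                "color": dataclasses.asdict(self.spec.color),
                "diamond_width_px": self.spec.diamond_width_px,
                "positional_setting": self.spec.positional_setting,
                "canvas": dataclasses.asdict(self.spec.canvas),
            },
            "tilt_angles_deg": list(self.tilt.angles_deg) if self.tilt else None,
            "seed": self.seed,
        }
        return meta

    def save(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write the raster as PNG plus a JSON sidecar of its parameters."""
        path = Path(path)
        self.to_pil().save(path, format="PNG")
        if sidecar:
            path.with_suffix(".json").write_text(
                json.dumps(self.metadata(), indent=1)
            )
        return path


def default_color_ring() -> list[ColorSpec]:
    """The 12 hues of the RGB colour ring at 30-degree steps.

    Fully saturated, full value; ordered red -> rose by increasing hue.
    """
    ring = []
    for i, name in enumerate(_RING_NAMES):
        r, g, b = colorsys.hsv_to_rgb(i * 30.0 / 360.0, 1.0, 1.0)
        ring.append(
            ColorSpec(name=name, rgb=(round(r * 255), round(g * 255), round(b * 255)), ring_index=i)
        )
    return ring


def enumerate_stimulus_grid(
    palette: Sequence[ColorSpec] | None = None,
    widths: Iterable[int] = DEFAULT_DIAMOND_WIDTHS,
    settings: Iterable[str] = POSITIONAL_SETTINGS,
    canvas: CanvasSpec | None = None,
) -> list[StimulusSpec]:
    """Cartesian product of palette x diamond width x positional setting.

    Deterministic colour-major order; the defaults give the fixed
    144-combination grid (12 colours x 6 widths x 2 settings).
    """
    palette = list(default_color_ring() if palette is None else palette)
    widths = list(widths)
    settings = list(settings)
    if not palette or not widths or not settings:
        raise ValueError("palette, widths and settings must all be non-empty")
    canvas = canvas or CanvasSpec()
    return [
        StimulusSpec(color=c, diamond_width_px=w, positional_setting=s, canvas=canvas)
        for c, w, s in itertools.product(palette, widths, settings)
    ]


def _rotate(points: np.ndarray, center: tuple[float, float], angle_deg: float) -> np.ndarray:
    """Rotate Nx2 points about center; clockwise-positive in y-down coords."""
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    cx, cy = center
    d = points - (cx, cy)
    # y axis points down, so [c -s; s c] moves the right-hand end downward
    # for positive angles, i.e. a visually clockwise rotation.
    out = np.empty_like(d)
    out[:, 0] = c * d[:, 0] - s * d[:, 1]
    out[:, 1] = s * d[:, 0] + c * d[:, 1]
    return out + (cx, cy)


def _diamond_columns(spec: StimulusSpec) -> list[float]:
    """x centres of the diamond positions along one bar."""
    canvas = spec.canvas
    x0 = (canvas.width_px - canvas.bar_length_px) / 2.0
    pitch = canvas.diamond_pitch_px
    half = spec.diamond_width_px / math.sqrt(2.0)
    xs = []
    x = x0 + pitch / 2.0
    while x + half <= x0 + canvas.bar_length_px:
        if x - half >= x0:
            xs.append(x)
        x += pitch
    return xs


def _render(spec: StimulusSpec, tilt: TiltSpec) -> RenderedImage:
    canvas = spec.canvas
    half_diag = spec.diamond_width_px / math.sqrt(2.0)
    if half_diag > canvas.bar_thickness_px:
        raise ValueError(
            "diamond width exceeds the bar thickness budget: "
            f"half-diagonal {half_diag:.2f} px > thickness {canvas.bar_thickness_px} px"
        )
    if len(tilt.angles_deg) != canvas.bar_count:
        raise ValueError("one tilt angle per bar is required")

    ss = _SUPERSAMPLE
    W, H = canvas.width_px * ss, canvas.height_px * ss
    img = Image.new("RGB", (W, H), canvas.background_colors[0])
    draw = ImageDraw.Draw(img)

    # Vertical background stripes, alternating black/blue from the left edge.
    sw = canvas.background_stripe_width_px * ss
    for k in range(canvas.width_px // canvas.background_stripe_width_px + 1):
        color = canvas.background_colors[k % 2]
        draw.rectangle([k * sw, 0, (k + 1) * sw - 1, H - 1], fill=color)

    x0 = (canvas.width_px - canvas.bar_length_px) / 2.0
    x1 = x0 + canvas.bar_length_px
    ht = canvas.bar_thickness_px / 2.0
    swap = spec.positional_setting == "II"
    black, white = (0, 0, 0), (255, 255, 255)

    for b in range(canvas.bar_count):
        yc = canvas.height_px * (b + 0.5) / canvas.bar_count
        center = ((x0 + x1) / 2.0, yc)
        angle = tilt.angles_deg[b]

        def poly(points: np.ndarray, color: tuple[int, int, int]) -> None:
            pts = _rotate(points, center, angle) * ss
            draw.polygon([tuple(p) for p in pts], fill=color)

        bar_rect = np.array(
            [[x0, yc - ht], [x1, yc - ht], [x1, yc + ht], [x0, yc + ht]], dtype=float
        )
        poly(bar_rect, spec.color.rgb)

        # Diamonds straddle the bar's long edges; the black/white alternation
        # phase flips between the two positional settings and between the two
        # edges, producing the Café-Wall-like offset.
        for j, xc in enumerate(_diamond_columns(spec)):
            top_black = (j % 2 == 0) != swap
            for edge, is_top in ((yc - ht, True), (yc + ht, False)):
                col = black if (top_black == is_top) else white
                dia = np.array(
                    [
                        [xc, edge - half_diag],
                        [xc + half_diag, edge],
                        [xc, edge + half_diag],
                        [xc - half_diag, edge],
                    ],
                    dtype=float,
                )
                poly(dia, col)

    small = img.resize((canvas.width_px, canvas.height_px), Image.Resampling.BOX)
    return RenderedImage(pixels=np.asarray(small, dtype=np.uint8), spec=spec, tilt=tilt)


def render_illusion(spec: StimulusSpec) -> RenderedImage:
    """Render the illusion stimulus: physically horizontal bars."""
    img = _render(spec, TiltSpec.zero())
    return RenderedImage(pixels=img.pixels, spec=spec, tilt=None)


def render_tilted(spec: StimulusSpec, tilt: TiltSpec) -> RenderedImage:
    """Render the same scene with each bar rotated about its own centre.

    A zero tilt reproduces :func:`render_illusion` bit-identically.
    """
    return _render(spec, tilt)
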