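"""Dataset construction: tilted training images and illusion test images.

Manifests are plain :class:`pandas.DataFrame` tables in which every row
records the full generating parameters of one image (hue, diamond
width, positional setting, per-bar tilt angles, level, class, split), so
any manifest can be re-rendered bit-for-bit from (config, seed) without
storing pixels.  Images are materialised to PNG on demand or rendered
straight to arrays for training.

The training pool contains, per strength level k = 1..8, images whose
bars are genuinely tilted by a magnitude drawn uniformly from level k's
0.1-degree bin, signed by the stimulus's positional setting; stimulus
parameters are sampled independently of the label so the tilt is the
only label-correlated signal.  The illusion test set renders the fixed
stimulus grid with physically horizontal bars, labelled by perceived
strength.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import human
from .human import N_LEVELS, LEVEL_WIDTH_DEG, StrengthRecord, assign_class
from .stimuli import (
    DEFAULT_DIAMOND_WIDTHS,
    POSITIONAL_SETTINGS,
    CanvasSpec,
    ColorSpec,
    StimulusSpec,
    TiltSpec,
    default_color_ring,
    render_illusion,
    render_tilted,
)
from .utils import derive_rng

__all__ = [
    "MANIFEST_COLUMNS",
    "build_training_pool",
    "split_train_val",
    "build_independent_test",
    "build_illusion_test",
    "row_to_spec",
    "render_row",
    "materialize",
    "manifest_to_arrays",
    "write_manifest",
    "read_manifest",
]

MANIFEST_COLUMNS = [
    "image_path",
    "split",
    "class_label",
    "level",
    "stimulus_id",
    "color",
    "diamond_width_px",
    "positional_setting",
    "tilt1",
    "tilt2",
    "tilt3",
    "tilt4",
]


def _sample_rows(
    n_per_level: int,
    seed: int,
    stream: str,
    split: str,
    prefix: str,
    palette: Sequence[ColorSpec],
    widths: Sequence[int],
    jitter_sd_deg: float,
    counts: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Sample per-level image parameter rows from a named seed stream."""
    rng = derive_rng(seed, stream)
    names = [c.name for c in palette]
    rows = []
    for k in range(1, N_LEVELS + 1):
        n_k = n_per_level if counts is None else counts[k - 1]
        for i in range(n_k):
            color = names[rng.integers(len(names))]
            width = widths[rng.integers(len(widths))]
            setting = POSITIONAL_SETTINGS[rng.integers(2)]
            # uniform on ((k-1)*0.1, k*0.1]: 1-u maps [0,1) onto (0,1]
            mag = (k - 1 + (1.0 - rng.random())) * LEVEL_WIDTH_DEG
            sign = 1.0 if setting == "I" else -1.0
            tilts = np.full(4, sign * mag)
            if jitter_sd_deg > 0:
                tilts = tilts + rng.normal(0.0, jitter_sd_deg, size=4)
            rows.append(
                {
                    "image_path": f"{prefix}/level{k}_{i:05d}.png",
                    "split": split,
                    "class_label": assign_class(k),
                    "level": k,
                    "stimulus_id": "",
                    "color": color,
                    "diamond_width_px": int(width),
                    "positional_setting": setting,
                    "tilt1": tilts[0],
                    "tilt2": tilts[1],
                    "tilt3": tilts[2],
                    "tilt4": tilts[3],
                }
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def build_training_pool(
    per_level: int,
    seed: int,
    palette: Sequence[ColorSpec] | None = None,
    widths: Sequence[int] = DEFAULT_DIAMOND_WIDTHS,
    jitter_sd_deg: float = 0.0,
) -> pd.DataFrame:
    """``per_level`` tilted images for each of the 8 strength levels.

    The default scale, per_level = 3000, yields 24,000 images with
    exactly 12,000 per class.
    """
    if per_level <= 0:
        raise ValueError("per_level must be positive")
    palette = list(default_color_ring() if palette is None else palette)
    return _sample_rows(
        per_level, seed, "training_pool", "pool", "train", palette, widths, jitter_sd_deg
    )


def split_train_val(
    manifest: pd.DataFrame, ratio: tuple[int, int] = (3, 1), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/validation split at an a:b ratio.

    Stratification is by level (which fixes the class); per stratum the
    train share is within one row of the exact a/(a+b) proportion.  The
    two outputs are disjoint and their union is the input.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    a, b = ratio
    if a < 1 or b < 1:
        raise ValueError("ratio parts must be >= 1")
    rng = derive_rng(seed, "split_train_val")
    train_idx: list[int] = []
    val_idx: list[int] = []
    for _, group in manifest.groupby("level", sort=True):
        idx = group.index.to_numpy()
        rng.shuffle(idx)
        n_train = int(round(len(idx) * a / (a + b)))
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    train = manifest.loc[sorted(train_idx)].assign(split="train")
    val = manifest.loc[sorted(val_idx)].assign(split="val")
    return train.reset_index(drop=True), val.reset_index(drop=True)


def build_independent_test(
    n: int,
    seed: int,
    palette: Sequence[ColorSpec] | None = None,
    widths: Sequence[int] = DEFAULT_DIAMOND_WIDTHS,
    jitter_sd_deg: float = 0.0,
) -> pd.DataFrame:
    """An independent tilted test set of ``n`` images, balanced by level.

    Drawn from a seed stream disjoint from the training pool's, so the
    sampled parameter vectors never coincide with training rows.
    """
    if n < 2 or n % 2:
        raise ValueError("n must be an even integer >= 2")
    palette = list(default_color_ring() if palette is None else palette)
    counts = [n // N_LEVELS + (1 if k < n % N_LEVELS else 0) for k in range(N_LEVELS)]
    return _sample_rows(
        0, seed, "independent_test", "test_tilted", "test", palette, widths,
        jitter_sd_deg, counts=counts,
    )


def build_illusion_test(
    strengths: Sequence[StrengthRecord],
) -> pd.DataFrame:
    """The illusion test set: every grid stimulus, horizontal bars.

    Labels come from the per-stimulus perceived strengths; tilt columns
    are empty because the bars are physically horizontal.
    """
    if not strengths:
        raise ValueError("no strength records supplied")
    seen = set()
    rows = []
    for rec in strengths:
        sid = rec.stimulus.stimulus_id
        if sid in seen:
            raise ValueError(f"duplicate strength record for stimulus {sid}")
        seen.add(sid)
        rows.append(
            {
                "image_path": f"illusion/{sid}.png",
                "split": "test_illusion",
                "class_label": rec.illusion_class,
                "level": rec.level,
                "stimulus_id": sid,
                "color": rec.stimulus.color.name,
                "diamond_width_px": rec.stimulus.diamond_width_px,
                "positional_setting": rec.stimulus.positional_setting,
                "tilt1": np.nan,
                "tilt2": np.nan,
                "tilt3": np.nan,
                "tilt4": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


# ---------------------------------------------------------------------------
# Rendering manifests


def row_to_spec(
    row, palette: Sequence[ColorSpec] | None = None, canvas: CanvasSpec | None = None
) -> tuple[StimulusSpec, TiltSpec | None]:
    """Reconstruct the stimulus and tilt of one manifest row."""
    palette = list(default_color_ring() if palette is None else palette)
    by_name = {c.name: c for c in palette}
    color = by_name[row.color]
    spec = StimulusSpec(
        color=color,
        diamond_width_px=int(row.diamond_width_px),
        positional_setting=str(row.positional_setting),
        canvas=canvas or CanvasSpec(),
    )
    if pd.isna(row.tilt1):
        return spec, None
    tilt = TiltSpec((float(row.tilt1), float(row.tilt2), float(row.tilt3), float(row.tilt4)))
    return spec, tilt


def render_row(
    row, palette: Sequence[ColorSpec] | None = None, canvas: CanvasSpec | None = None
):
    spec, tilt = row_to_spec(row, palette, canvas)
    return render_illusion(spec) if tilt is None else render_tilted(spec, tilt)


def materialize(
    manifest: pd.DataFrame,
    out_dir: str | Path,
    palette: Sequence[ColorSpec] | None = None,
    canvas: CanvasSpec | None = None,
    sidecar: bool = False,
) -> pd.DataFrame:
    """Render every row to PNG under ``out_dir``; returns the manifest
    with absolute image paths."""
    out_dir = Path(out_dir)
    paths = []
    for row in manifest.itertuples(index=False):
        img = render_row(row, palette, canvas)
        path = out_dir / row.image_path
        path.parent.mkdir(parents=True, exist_ok=True)
        img.save(path, sidecar=sidecar)
        paths.append(str(path))
    out = manifest.copy()
    out["image_path"] = paths
    return out


def manifest_to_arrays(
    manifest: pd.DataFrame,
    downscale: int = 1,
    palette: Sequence[ColorSpec] | None = None,
    canvas: CanvasSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a manifest straight to (X, y) arrays for the classifier.

    X is N x H x W x 3 uint8 (NHWC), optionally box-downscaled by an
    integer factor; y is 0 for C1 and 1 for C2.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    imgs = []
    for row in manifest.itertuples(index=False):
        img = render_row(row, palette, canvas)
        pix = img.pixels
        if downscale > 1:
            h, w = pix.shape[0] // downscale, pix.shape[1] // downscale
            pix = np.asarray(
                img.to_pil().resize((w, h), Image.Resampling.BOX), dtype=np.uint8
            )
        imgs.append(pix)
    X = np.stack(imgs)
    y = (manifest["class_label"].to_numpy() == "C2").astype(np.int64)
    return X, y


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df["stimulus_id"] = df["stimulus_id"].fillna("")
    return df
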