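"""Cross-set representational dissimilarity between perceived-tilt and
illusion renders.

For each strength level 1..8 an exemplar grid stimulus is chosen (the
one whose perceived strength lies nearest the level's bin centre) and
rendered twice: physically horizontal (the illusion image) and at its
perceived angles (the perceived-tilt image).  Features are extracted at
named network taps and compared with the L2 distance, giving an 8 x 8
cross-set matrix r per depth whose rows are perceived-tilt levels and
columns illusion levels; the normalised matrix R = r / mean(r) has unit
mean by construction, so depths can be compared on a common scale.

Two distance modes are provided: ``sq_sum`` (the summed squared
difference) and ``euclidean`` (its square root, the default).  Because
the normalisation by the matrix mean is not invariant to that choice,
the mode is recorded in every output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harness import HyperParams, predict
from .human import StrengthRecord, N_LEVELS, LEVEL_WIDTH_DEG
from .nn import Network
from .saliency import HeatMap, _image_to_input
from .stimuli import RenderedImage, TiltSpec, render_illusion, render_tilted

__all__ = [
    "FeatureTensor",
    "CrossRDM",
    "FrameworkScore",
    "extract_features",
    "pair_distance",
    "select_level_exemplars",
    "render_level_pairs",
    "build_cross_rdm",
    "depth_profile",
    "diagonal_contrast",
    "framework_score",
]

DISTANCE_MODES = ("sq_sum", "euclidean")


@dataclass(frozen=True)
class FeatureTensor:
    """Activations of one image at one named layer tap."""

    values: np.ndarray
    layer_id: str
    source_kind: str  # "perceived" | "real"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


@dataclass(frozen=True)
class CrossRDM:
    """8 x 8 cross-set dissimilarity at one depth.

    Rows are perceived-tilt renders by level, columns illusion renders
    by level; ``r`` holds raw distances and ``R = r / mean(r)`` has mean
    exactly 1 (an all-zero ``r`` normalises to all ones).
    """

    r: np.ndarray
    R: np.ndarray
    layer_id: str
    mode: str
    row_levels: tuple[int, ...] = tuple(range(1, N_LEVELS + 1))
    col_levels: tuple[int, ...] = tuple(range(1, N_LEVELS + 1))


@dataclass(frozen=True)
class FrameworkScore:
    """Synthesis of the Grad-CAM and RDM evidence into one number."""

    S_DNN: float
    components: dict[str, float]
    synthesis_name: str


def extract_features(
    model: Network,
    image: RenderedImage | np.ndarray,
    layer_id: str,
    source_kind: str = "real",
    downscale: int = 2,
) -> FeatureTensor:
    """Deterministic evaluation-mode activations at a registered tap."""
    x = _image_to_input(image, downscale)
    _, taps = model.forward(x, taps=[layer_id])
    return FeatureTensor(values=taps[layer_id][0], layer_id=layer_id, source_kind=source_kind)


def pair_distance(
    a: FeatureTensor | np.ndarray, b: FeatureTensor | np.ndarray,
    mode: str = "euclidean",
) -> float:
    """L2 distance between two same-shape feature tensors.

    ``sq_sum`` is the summed squared difference; ``euclidean`` its
    square root.  Zero iff the tensors are identical.
    """
    if mode not in DISTANCE_MODES:
        raise ValueError(f"mode must be one of {DISTANCE_MODES}, got {mode!r}")
    va = a.values if isinstance(a, FeatureTensor) else np.asarray(a)
    vb = b.values if isinstance(b, FeatureTensor) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    if isinstance(a, FeatureTensor) and isinstance(b, FeatureTensor):
        if a.layer_id != b.layer_id:
            raise ValueError("feature tensors come from different layers")
    sq = float(np.sum((va.astype(np.float64) - vb.astype(np.float64)) ** 2))
    return sq if mode == "sq_sum" else float(np.sqrt(sq))


def select_level_exemplars(
    strengths: list[StrengthRecord],
) -> dict[int, StrengthRecord]:
    """One exemplar stimulus per level: nearest to the level's bin centre."""
    chosen: dict[int, StrengthRecord] = {}
    for level in range(1, N_LEVELS + 1):
        centre = (level - 0.5) * LEVEL_WIDTH_DEG
        candidates = [s for s in strengths if s.level == level]
        if not candidates:
            raise ValueError(
                f"no stimulus with strength level {level}; the cross-set RDM "
                "needs an exemplar for every level"
            )
        chosen[level] = min(candidates, key=lambda s: abs(s.strength_deg - centre))
    return chosen


def render_level_pairs(
    exemplars: dict[int, StrengthRecord],
) -> tuple[list[RenderedImage], list[RenderedImage]]:
    """(perceived-tilt renders, illusion renders), both ordered by level.

    The perceived-tilt render rotates all four bars by the stimulus's
    mean perceived angle, signed by its positional setting; the illusion
    render keeps the bars horizontal.
    """
    perceived, illusion = [], []
    for level in sorted(exemplars):
        rec = exemplars[level]
        sign = 1.0 if rec.stimulus.positional_setting == "I" else -1.0
        angle = sign * rec.strength_deg
        perceived.append(render_tilted(rec.stimulus, TiltSpec((angle,) * 4)))
        illusion.append(render_illusion(rec.stimulus))
    return perceived, illusion


def build_cross_rdm(
    model: Network,
    layer_id: str,
    perceived_images: list[RenderedImage] | list[np.ndarray],
    illusion_images: list[RenderedImage] | list[np.ndarray],
    mode: str = "euclidean",
    downscale: int = 2,
) -> CrossRDM:
    """r[i][j] = distance(perceived level i+1, illusion level j+1)."""
    if len(perceived_images) != N_LEVELS or len(illusion_images) != N_LEVELS:
        raise ValueError(
            f"exactly {N_LEVELS} images per set are required, got "
            f"{len(perceived_images)} and {len(illusion_images)}"
        )
    feats_p = [
        extract_features(model, im, layer_id, "perceived", downscale)
        for im in perceived_images
    ]
    feats_r = [
        extract_features(model, im, layer_id, "real", downscale)
        for im in illusion_images
    ]
    r = np.empty((N_LEVELS, N_LEVELS), np.float64)
    for i, fp in enumerate(feats_p):
        for j, fr in enumerate(feats_r):
            r[i, j] = pair_distance(fp, fr, mode)
    mean = r.mean()
    R = r / mean if mean > 0 else np.ones_like(r)
    return CrossRDM(r=r, R=R, layer_id=layer_id, mode=mode)


def depth_profile(
    model: Network,
    strengths: list[StrengthRecord],
    layers: list[str] | None = None,
    hp: HyperParams | None = None,
    mode: str = "euclidean",
) -> pd.DataFrame:
    """Mean perceived-vs-illusion distance per depth, stratified by the
    classifier's correctness and the true class.

    Every grid stimulus is rendered both physically horizontal and at
    its perceived angles; the model classifies the illusion render, and
    each (layer, stratum) cell averages the pair distances of the
    stimuli in that stratum.  Strata with no members are absent from the
    output.
    """
    if not strengths:
        raise ValueError("no strength records supplied")
    hp = hp or HyperParams()
    layers = layers or model.tap_points
    from .datasets import build_illusion_test, manifest_to_arrays

    manifest = build_illusion_test(strengths)
    X, _ = manifest_to_arrays(manifest, downscale=hp.downscale)
    pred = predict(model, manifest, hp, X=X)
    true = manifest["class_label"].to_numpy()

    rows = []
    dists: dict[str, list[tuple[str, float]]] = {lid: [] for lid in layers}
    for rec, p, t in zip(strengths, pred, true):
        sign = 1.0 if rec.stimulus.positional_setting == "I" else -1.0
        perceived = render_tilted(rec.stimulus, TiltSpec((sign * rec.strength_deg,) * 4))
        illusion = render_illusion(rec.stimulus)
        xs = _image_to_input(perceived, hp.downscale)
        xi = _image_to_input(illusion, hp.downscale)
        _, taps_p = model.forward(xs, taps=layers)
        _, taps_i = model.forward(xi, taps=layers)
        stratum = f"{'correct' if p == t else 'incorrect'}-{t}"
        for lid in layers:
            d = pair_distance(taps_p[lid][0], taps_i[lid][0], mode)
            dists[lid].append((stratum, d))
    for lid in layers:
        frame = pd.DataFrame(dists[lid], columns=["stratum", "distance"])
        for stratum, group in frame.groupby("stratum"):
            rows.append(
                {
                    "layer_id": lid,
                    "stratum": stratum,
                    "mean_distance": float(group["distance"].mean()),
                    "n": int(len(group)),
                }
            )
    return pd.DataFrame(rows)


def diagonal_contrast(rdm: CrossRDM) -> float:
    """Mean off-diagonal minus mean diagonal of the normalised matrix.

    Positive values mean matched-level pairs are more similar than
    mismatched ones (the diagonal structure the probe looks for at
    shallow depths)."""
    R = rdm.R
    diag = float(np.trace(R) / R.shape[0])
    off = float((R.sum() - np.trace(R)) / (R.size - R.shape[0]))
    return off - diag


def framework_score(
    heatmaps: dict[str, HeatMap],
    rdms: list[CrossRDM],
    synthesis_name: str = "diag_contrast_minus_spread",
    weights: tuple[float, float] = (0.5, 0.5),
) -> FrameworkScore:
    """Combine Grad-CAM and RDM evidence into a scalar sensitivity score.

    The default synthesis takes (a) the mean absolute difference of the
    min-max-normalised C1 and C2 heat maps and (b) the diagonal contrast
    of the earliest-depth RDM, and returns their weighted sum with the
    given (gradcam, rdm) weights.
    """
    if synthesis_name != "diag_contrast_minus_spread":
        raise ValueError(f"unknown synthesis {synthesis_name!r}")
    if not heatmaps or not rdms:
        raise ValueError("at least one heat map and one RDM are required")
    if set(heatmaps) != {"C1", "C2"}:
        raise ValueError("heatmaps must map exactly the classes C1 and C2")

    def norm(m: np.ndarray) -> np.ndarray:
        rng_ = m.max() - m.min()
        return np.zeros_like(m) if rng_ == 0 else (m - m.min()) / rng_

    a, b = norm(heatmaps["C1"].L), norm(heatmaps["C2"].L)
    if a.shape != b.shape:
        raise ValueError("C1 and C2 heat maps must share a shape")
    gradcam_summary = float(np.abs(a - b).mean())
    rdm_summary = diagonal_contrast(rdms[0])
    w_g, w_r = weights
    return FrameworkScore(
        S_DNN=w_g * gradcam_summary + w_r * rdm_summary,
        components={"gradcam_summary": gradcam_summary, "rdm_summary": rdm_summary},
        synthesis_name=synthesis_name,
    )
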