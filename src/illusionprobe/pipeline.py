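"""End-to-end orchestration: one config + one seed -> a full run.

The pipeline chains every stage of the probe — stimulus grid, synthetic
perceptual data, strength scoring, dataset construction, classifier
training, evaluation, permutation significance, Grad-CAM, cross-set
RDMs, depth profile and the framework score — and writes all artefacts
(CSV manifests, the angle table, the trained weights, JSON reports)
under one output directory.  Every random draw fans out from the single
config seed through named streams, so re-running the same config in a
fresh process reproduces every artefact.

Stage failures are re-raised as :class:`PipelineError` whose message
names the stage (``run_all:<stage>``), so a failed run points at the
responsible step rather than a bare traceback.

Config schema (YAML mapping; all keys optional, defaults below)::

    seed: 0                  # master seed, fans out to every stage
    out_dir: results/run     # artefact directory, created if absent
    arch: desknet            # key in harness.ARCH_REGISTRY
    per_level: 40            # training-pool images per strength level
    test_n: 160              # independent tilted test images (even)
    train_val_ratio: [3, 1]  # stratified split proportions
    n_participants: 23       # synthetic adjustment-task participants
    participant_sd_deg: 0.1  # per-bar response noise (deg)
    n_permutations: 5        # label-shuffle retrainings for the null
    rdm_mode: euclidean      # or sq_sum
    epochs: 10               # plus any other HyperParams field:
    downscale: 2             #   initial_lr, lr_decay_factor,
    batch_size: 32           #   lr_decay_every_epochs, weight_decay,
                             #   dropout_rate, optimizer
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from . import datasets, harness, human, representation, saliency, stimuli
from .utils import derive_seed

__all__ = ["RunConfig", "PipelineError", "load_config", "run_all"]

_HP_FIELDS = {f.name for f in fields(harness.HyperParams)} - {"seed"}


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of one full pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    arch: str = "desknet"
    per_level: int = 40
    test_n: int = 160
    train_val_ratio: tuple[int, int] = (3, 1)
    n_participants: int = 23
    participant_sd_deg: float = 0.1
    n_permutations: int = 5
    rdm_mode: str = "euclidean"
    hyperparams: harness.HyperParams = field(default_factory=harness.HyperParams)

    def __post_init__(self) -> None:
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be in [0, 2**31)")
        if self.arch not in harness.ARCH_REGISTRY:
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.per_level < 1:
            raise ValueError("per_level must be >= 1")
        if self.test_n < 2 or self.test_n % 2:
            raise ValueError("test_n must be an even integer >= 2")
        if len(self.train_val_ratio) != 2 or min(self.train_val_ratio) < 1:
            raise ValueError("train_val_ratio must be two integers >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.rdm_mode not in representation.DISTANCE_MODES:
            raise ValueError(
                f"rdm_mode must be one of {representation.DISTANCE_MODES}"
            )


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run config (see module docstring)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(RunConfig)} - {"hyperparams"}
    unknown = set(raw) - known - _HP_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    hp_kwargs = {k: raw.pop(k) for k in list(raw) if k in _HP_FIELDS}
    if "train_val_ratio" in raw:
        raw["train_val_ratio"] = tuple(raw["train_val_ratio"])
    cfg = RunConfig(**raw)
    hp = replace(cfg.hyperparams, **hp_kwargs)
    return replace(cfg, hyperparams=hp)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"run_all:{name}: {exc}") from exc
        return inner
    return wrap


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the JSON-serialisable run report.

    Artefacts written under ``config.out_dir``: ``angles.csv``,
    ``strengths.csv``, ``train.csv`` / ``val.csv`` / ``test_tilted.csv``
    / ``test_illusion.csv`` (manifests), ``model.npz``,
    ``training_log.csv``, ``rdm_<layer>.csv``, ``gradcam_<class>.png``,
    ``depth_profile.csv`` and ``run_report.json``.
    """
    out = Path(config.out_dir)
    hp = replace(config.hyperparams, seed=derive_seed(config.seed, "train"))
    report: dict = {"config": _config_dict(config)}

    @_stage("setup")
    def setup():
        out.mkdir(parents=True, exist_ok=True)
        return stimuli.enumerate_stimulus_grid()

    grid = setup()

    @_stage("simulate")
    def simulate():
        params = human.ResponseModelParams(
            participant_sd_deg=config.participant_sd_deg,
            n_participants=config.n_participants,
            seed=derive_seed(config.seed, "simulate"),
        )
        records = human.simulate_responses(grid, params)
        human.write_angle_csv(records, out / "angles.csv")
        strengths = human.aggregate_strengths(records)
        human.strengths_to_frame(strengths).to_csv(out / "strengths.csv", index=False)
        return strengths

    strengths = simulate()
    report["n_stimuli"] = len(strengths)
    report["class_counts"] = {
        c: sum(1 for s in strengths if s.illusion_class == c) for c in ("C1", "C2")
    }

    @_stage("datasets")
    def build():
        pool = datasets.build_training_pool(
            config.per_level, seed=derive_seed(config.seed, "pool")
        )
        train_m, val_m = datasets.split_train_val(
            pool, config.train_val_ratio, seed=derive_seed(config.seed, "split")
        )
        test_m = datasets.build_independent_test(
            config.test_n, seed=derive_seed(config.seed, "independent_test")
        )
        illusion_m = datasets.build_illusion_test(strengths)
        for name, m in (
            ("train", train_m),
            ("val", val_m),
            ("test_tilted", test_m),
            ("test_illusion", illusion_m),
        ):
            datasets.write_manifest(m, out / f"{name}.csv")
        return train_m, val_m, test_m, illusion_m

    train_m, val_m, test_m, illusion_m = build()
    report["dataset_sizes"] = {
        "train": len(train_m),
        "val": len(val_m),
        "test_tilted": len(test_m),
        "test_illusion": len(illusion_m),
    }

    @_stage("train")
    def fit():
        Xtr, ytr = datasets.manifest_to_arrays(train_m, downscale=hp.downscale)
        Xva, yva = datasets.manifest_to_arrays(val_m, downscale=hp.downscale)
        model = harness.make_model(
            config.arch,
            seed=hp.seed,
            dropout_rate=hp.dropout_rate,
            input_hw=Xtr.shape[1:3],
        )
        log = harness.train(model, train_m, val_m, hp, data=((Xtr, ytr), (Xva, yva)))
        log.to_csv(out / "training_log.csv", index=False)
        model.save(out / "model.npz")
        return model, log

    model, log = fit()
    report["final_train_acc"] = float(log["train_acc"].iloc[-1])
    report["final_val_acc"] = float(log["val_acc"].iloc[-1])

    @_stage("evaluate")
    def score():
        tilted = harness.evaluate(model, test_m, hp)
        illusion = harness.evaluate(model, illusion_m, hp)
        return tilted, illusion

    tilted_metrics, illusion_metrics = score()
    report["test_tilted"] = tilted_metrics.to_dict()
    report["test_illusion"] = illusion_metrics.to_dict()

    @_stage("permtest")
    def permtest():
        return harness.permutation_test(
            config.arch, train_m, val_m, test_m, hp,
            n_perms=config.n_permutations, force=True,
        )

    perm = permtest()
    report["permutation_test"] = {
        "n_permutations": config.n_permutations,
        "null_accuracies": list(perm.null_accuracies),
        "percentile95": perm.percentile95,
        "actual_accuracy": perm.actual_accuracy,
        "significant": perm.significant,
    }

    @_stage("gradcam")
    def cams():
        exemplars = representation.select_level_exemplars(strengths)
        # class-prototypical illusion stimuli: weakest (level 1) for C1,
        # strongest (level 8) for C2
        chosen = {"C1": exemplars[1], "C2": exemplars[8]}
        maps = {}
        for class_id, rec in chosen.items():
            img = stimuli.render_illusion(rec.stimulus)
            hm = saliency.gradcam(model, img, class_id, downscale=hp.downscale)
            overlay = saliency.heatmap_overlay(hm, img)
            from PIL import Image

            Image.fromarray(overlay.pixels).save(out / f"gradcam_{class_id}.png")
            maps[class_id] = hm
        return exemplars, maps

    exemplars, heatmaps = cams()
    report["gradcam"] = {
        c: {"layer_id": h.layer_id, "max": float(h.L.max())}
        for c, h in heatmaps.items()
    }

    @_stage("rdm")
    def rdms():
        perceived, illusion = representation.render_level_pairs(exemplars)
        out_rdms = []
        for layer in model.tap_points:
            rdm = representation.build_cross_rdm(
                model, layer, perceived, illusion,
                mode=config.rdm_mode, downscale=hp.downscale,
            )
            np.savetxt(out / f"rdm_{layer}.csv", rdm.R, delimiter=",")
            out_rdms.append(rdm)
        profile = representation.depth_profile(
            model, strengths, hp=hp, mode=config.rdm_mode
        )
        profile.to_csv(out / "depth_profile.csv", index=False)
        return out_rdms, profile

    rdm_list, profile = rdms()
    report["rdm"] = {
        rdm.layer_id: {
            "mode": rdm.mode,
            "mean_R": float(rdm.R.mean()),
            "diagonal_contrast": representation.diagonal_contrast(rdm),
        }
        for rdm in rdm_list
    }
    report["depth_profile"] = profile.to_dict(orient="records")

    @_stage("framework_score")
    def synthesize():
        return representation.framework_score(heatmaps, rdm_list)

    fs = synthesize()
    report["framework_score"] = {
        "S_DNN": fs.S_DNN,
        "components": fs.components,
        "synthesis": fs.synthesis_name,
    }

    @_stage("report")
    def write_report():
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2)

    write_report()
    return report


def _config_dict(config: RunConfig) -> dict:
    d = {
        f.name: getattr(config, f.name)
        for f in fields(RunConfig)
        if f.name != "hyperparams"
    }
    d["train_val_ratio"] = list(config.train_val_ratio)
    d["hyperparams"] = {
        f.name: getattr(config.hyperparams, f.name)
        for f in fields(harness.HyperParams)
    }
    return d
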