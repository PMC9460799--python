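"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate ->
explain -> analyze, with one JSON config and a run directory of artifacts.

Every stage seed is derived deterministically from the master seed, so a run
directory can be reproduced bit-identically from its resolved config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import features as feat
from . import gradcam as gc
from . import imaging, synthetic
from .nn import INPUT_SHAPES, build_model
from .training import (
    CLASSES,
    TrainConfig,
    evaluate,
    frames_to_arrays,
    make_folds,
    train_model,
)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "preprocess", "train", "evaluate", "gradcam", "features")


@dataclass
class RunConfig:
    input_type: str = "eye"  # face | eye | fusion | eye+gender
    target: str = "drowsy"  # drowsy | gender
    n_subjects: int = 20
    frames_per_subject: int = 10
    n_iterations: int = 4
    margin: float = 0.25
    max_steps: int = 2000
    batch_size: int = 32
    gradcam_samples: int = 8
    seed: int = 0
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    train: dict = field(default_factory=dict)  # extra TrainConfig overrides

    def __post_init__(self):
        if self.input_type not in imaging.INPUT_TYPES:
            raise ValueError(f"unknown input_type {self.input_type!r}")
        if self.target not in ("drowsy", "gender"):
            raise ValueError(f"unknown target {self.target!r}")

    @property
    def input_shape(self):
        return INPUT_SHAPES[self.input_type]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        gen = d.pop("generator", {})
        if "image_size" in gen:
            gen["image_size"] = tuple(gen["image_size"])
        return cls(generator=synthetic.GeneratorConfig(**gen), **d)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _target_labels(frames, target: str):
    if target == "drowsy":
        return [f.label for f in frames], CLASSES
    return [f.gender for f in frames], ("male", "female")


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 dry_run: bool = False, log=print) -> dict:
    """Run every stage and return (and optionally write) the summary dict.

    With ``dry_run`` the config is validated and the stage plan printed, but
    nothing is computed.
    """
    if dry_run:
        log(f"run plan: {' -> '.join(STAGES)}")
        log(config.to_json())
        return {"dry_run": True, "stages": list(STAGES)}

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())

    stage = "simulate"
    try:
        frames, manifest = synthetic.generate_dataset(
            config.n_subjects, config.frames_per_subject,
            config=config.generator, seed=config.seed,
        )
        if out is not None:
            manifest.to_csv(out / "manifest.csv", index=False)

        stage = "preprocess"
        inputs = [
            imaging.preprocess_frame(f.image, f.landmarks, config.input_type,
                                     gender=f.gender, margin=config.margin)
            for f in frames
        ]
        labels, classes = _target_labels(frames, config.target)
        x, y = frames_to_arrays(inputs, labels, classes=classes)
        subject_ids = manifest["subject_id"].to_numpy()

        stage = "train"
        fold_manifest = manifest.copy()
        if config.target == "gender":
            fold_manifest["label"] = fold_manifest["gender"]
        folds = make_folds(fold_manifest, seed=config.seed + 1,
                           n_iterations=config.n_iterations)
        tc_kwargs = dict(max_steps=config.max_steps, batch_size=config.batch_size)
        tc_kwargs.update(config.train)
        iteration_reports = []
        networks = []
        for fold in folds:
            tc = TrainConfig.for_input_type(
                config.input_type, seed=config.seed + 200 + fold.iteration_index,
                **tc_kwargs,
            )
            net = build_model(config.input_type,
                              seed=config.seed + 100 + fold.iteration_index)
            tr = np.isin(subject_ids, list(fold.train_subjects))
            te = np.isin(subject_ids, list(fold.test_subjects))
            tlog = train_model(net, x[tr], y[tr], tc)
            report = evaluate(net, x[te], y[te], operating_point=tc.operating_point)
            iteration_reports.append((fold, net, report))
            networks.append(net)
            if out is not None:
                i = fold.iteration_index
                (out / f"eval_iter{i}.json").write_text(report.to_json())
                np.savetxt(out / f"roc_iter{i}.csv", np.array(report.roc_points),
                           delimiter=",", header="fpr,tpr", comments="")
                tlog.to_frame().to_csv(out / f"train_log_iter{i}.csv", index=False)
            log(f"iteration {fold.iteration_index}: "
                f"avg acc {report.average_accuracy:.2f}%, AUC {report.auc:.3f}")

        stage = "evaluate"
        aucs = [r.auc for _, _, r in iteration_reports]
        avg_accs = [r.average_accuracy for _, _, r in iteration_reports]
        best_idx = int(np.argmax(aucs))
        best_fold, best_net, _ = iteration_reports[best_idx]
        te = np.isin(subject_ids, list(best_fold.test_subjects))
        if out is not None:
            best_net.save_weights(out / "model_best.npz")
            (out / "parameter_counts.json").write_text(
                json.dumps(best_net.count_parameters().to_dict(), indent=2))

        stage = "gradcam"
        te_idx = np.nonzero(te)[0][: config.gradcam_samples]
        attention = []
        for i in te_idx:
            f = frames[i]
            _, mask = imaging.preprocess_frame(
                f.image, f.landmarks, config.input_type, gender=f.gender,
                margin=config.margin, mask=f.sclera_mask,
            )
            hm = gc.compute_gradcam(best_net, x[i])
            score = gc.attention_fraction(hm, mask)
            attention.append({"frame": int(i), "class_index": hm.class_index,
                              "mask_fraction": score.mask_fraction,
                              "mask_area_fraction": score.mask_area_fraction})
            if out is not None:
                overlay = gc.render_overlay(hm.upsampled_map, x[i])
                import imageio.v3 as iio

                iio.imwrite(out / f"gradcam_{i:04d}.png", overlay)
        if out is not None:
            (out / "attention.json").write_text(json.dumps(attention, indent=2))

        stage = "features"
        fm = feat.extract_features(best_net, x[te],
                                   np.asarray(labels)[te], subject_ids[te])
        proj = feat.pca_project(fm)
        curve = feat.knn_sigma_curve(fm)
        if out is not None:
            fm.to_csv(out / "features.csv")
            curve.to_csv(out / "knn_sigma.csv")
            fig = feat.plot_feature_cloud(proj, fm.labels)
            fig.savefig(out / "feature_cloud.png", dpi=100)
            import matplotlib.pyplot as plt

            plt.close(fig)
    except Exception as e:  # noqa: BLE001 - tag stage and re-raise
        raise StageError(stage, e) from e

    summary = {
        "config": json.loads(config.to_json()),
        "iterations": [
            {"iteration": f.iteration_index, "auc": r.auc,
             "average_accuracy": r.average_accuracy,
             "per_class_accuracy": r.per_class_accuracy}
            for f, _, r in iteration_reports
        ],
        "mean_auc": float(np.mean(aucs)),
        "best_iteration_auc": float(aucs[best_idx]),
        "mean_average_accuracy": float(np.mean(avg_accs)),
        "attention": attention,
        "knn_sigma_summary_P": curve.summary_P,
        "pca_eigenvalues": proj.eigenvalues.tolist(),
    }
    if out is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
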