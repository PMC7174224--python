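"""End-to-end experiment orchestration.

Glues the stages together: synthesize (or load) a labeled image set,
preprocess each image, extract the 120-entry feature vector (21 color +
99 texture), run the 22-classifier repeated-CV benchmark, and summarize
with accuracy tables, per-class rates, one-vs-rest AUCs and an
ANOVA + Duncan grouping. Every run is reproducible from its config and
master seed; the output manifest records a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import imageio.v3 as iio
import yaml

from . import classify, colorfeat, evaluate, preprocess, synthetic, texturefeat
from .classify import CvConfig, ModelSpec
from .colorfeat import ColorParams
from .preprocess import PreprocessParams
from .texturefeat import TextureParams

__all__ = ["RunConfig", "feature_names", "extract_features", "build_feature_table",
           "run_experiment", "config_hash", "save_config", "load_config"]

log = logging.getLogger("saffronvision")


@dataclass(frozen=True)
class RunConfig:
    """Complete description of one experiment."""

    counts: dict[str, int] = field(default_factory=lambda: {"Pushal": 30, "Negin": 30, "Sargol": 30})
    manifest_path: str | None = None  # if set, load images instead of synthesizing
    preprocess: PreprocessParams = field(default_factory=lambda: PreprocessParams(
        min_component_area=64, structuring_radius=2))
    color: ColorParams = field(default_factory=ColorParams)
    texture: TextureParams = field(default_factory=TextureParams)
    cv: CvConfig = field(default_factory=CvConfig)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {"preprocess": PreprocessParams, "color": ColorParams,
               "texture": TextureParams, "cv": CvConfig}
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                kwargs = dict(d[key])
                for f_ in dataclasses.fields(typ):
                    if f_.name in kwargs and isinstance(kwargs[f_.name], list):
                        kwargs[f_.name] = tuple(kwargs[f_.name])
                d[key] = typ(**kwargs)
        return cls(**d)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the configuration: changes iff a parameter that can
    affect the results does (the output directory is excluded)."""
    d = config.to_dict()
    d.pop("out_dir", None)
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def save_config(config: RunConfig, path: str) -> None:
    """Write the experiment configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_listify(config.to_dict()), fh, sort_keys=True)


def load_config(path: str) -> RunConfig:
    """Load a YAML configuration; round-trips :func:`save_config` exactly."""
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def feature_names(color: ColorParams = ColorParams(),
                  texture: TextureParams = TextureParams()) -> list[str]:
    """The 120 feature names in table order: 21 color then 99 texture."""
    return colorfeat.color_feature_names(color) + texturefeat.texture_feature_names(texture)


def extract_features(
    image,
    pre: PreprocessParams = PreprocessParams(),
    color: ColorParams = ColorParams(),
    texture: TextureParams = TextureParams(),
) -> pd.Series:
    """Preprocess one image (path or array) and compute its 120 features."""
    if isinstance(image, (str, os.PathLike)):
        image = np.asarray(iio.imread(image))[..., :3]
    cropped, mask, window = preprocess.preprocess_image(image, pre)
    log.debug("crop window %s, foreground px %d", window, int(mask.sum()))
    block = colorfeat.color_feature_block(cropped, mask, color)
    gray = texturefeat.to_gray(cropped)
    block.update(texturefeat.texture_feature_block(gray, mask, texture))
    names = feature_names(color, texture)
    return pd.Series([block[n] for n in names], index=names, dtype=np.float64)


def build_feature_table(config: RunConfig) -> pd.DataFrame:
    """Feature table for the configured image set (synthetic or from disk).

    Rows whose foreground vanishes after preprocessing are excluded with a
    logged reason. Columns: sample_id, class, then the 120 features.
    """
    if config.manifest_path:
        manifest = pd.read_csv(config.manifest_path)
        images = list(manifest["path"])
    else:
        scenes, manifest = synthetic.generate_dataset(config.counts, seed=config.seed)
        images = [img for img, _ in scenes]
    rows = []
    for (_, meta), image in zip(manifest.iterrows(), images):
        try:
            feats = extract_features(image, config.preprocess, config.color, config.texture)
        except ValueError as exc:
            log.warning("sample %s excluded: %s", meta["sample_id"], exc)
            continue
        row = {"sample_id": meta["sample_id"], "class": meta["class"]}
        row.update(feats.to_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("no sample survived preprocessing")
    return table


def run_experiment(
    config: RunConfig,
    suite: list[ModelSpec] | None = None,
    feature_table: pd.DataFrame | None = None,
) -> dict:
    """Run the full benchmark and return (and optionally write) the report bundle.

    The bundle holds the feature table, per-classifier CV results, the
    ranked accuracy summary, pooled-first-repetition rate tables, per-class
    and overall AUCs, and the ANOVA + Duncan letter display over the
    per-repetition accuracies.
    """
    suite = suite if suite is not None else classify.model_suite()
    table = feature_table if feature_table is not None else build_feature_table(config)
    feat_cols = [c for c in table.columns if c not in ("sample_id", "class")]
    X = table[feat_cols]
    y = table["class"].to_numpy()

    results: dict[str, classify.CvResult] = {}
    for spec in suite:
        log.info("cross-validating %s", spec.name)
        results[spec.id] = classify.run_cv(X, y, spec, config.cv)

    summary = pd.DataFrame(
        [{"id": s.id, "classifier": s.name, "family": s.family,
          "mean_accuracy_pct": results[s.id].mean_accuracy,
          "sd_accuracy_pct": results[s.id].sd_accuracy}
         for s in suite]
    ).sort_values("mean_accuracy_pct", ascending=False).reset_index(drop=True)

    classes = [c for c in evaluate.CLASS_ORDER if c in set(y)] or sorted(set(y))
    rates, aucs = {}, {}
    for s in suite:
        res = results[s.id]
        cm = evaluate.confusion(y, res.oof_predictions[0], classes=classes)
        rates[s.id] = evaluate.class_rates(cm).as_frame()
        per_class = {}
        score_col = {c: j for j, c in enumerate(res.classes)}
        for c in classes:
            try:
                _, auc = evaluate.roc_auc(res.oof_scores[0][:, score_col[c]], y, c)
            except ValueError:
                auc = np.nan
            per_class[c] = auc
        per_class["Overall"] = float(np.nanmean([per_class[c] for c in classes]))
        aucs[s.id] = per_class

    name_of = {s.id: s.name for s in suite}
    acc_groups = {name_of[sid]: np.array(r.accuracies) for sid, r in results.items()}
    duncan = None
    if len(acc_groups) >= 2 and config.cv.repetitions >= 2:
        F, dfb, dfw, ems, p = evaluate.anova_oneway(acc_groups)
    else:  # a single classifier (or single repetition) cannot be compared
        F = dfb = dfw = ems = p = np.nan
    if np.isfinite(F) and ems > 0:
        duncan = evaluate.duncan_groups(
            {k: float(v.mean()) for k, v in acc_groups.items()},
            n_per_group=config.cv.repetitions,
            error_mean_square=ems, df_within=dfw, alpha=config.alpha,
        )

    bundle = {
        "config": config, "config_hash": config_hash(config),
        "feature_table": table, "cv_results": results, "summary": summary,
        "rates": rates, "aucs": aucs,
        "anova": {"F": F, "df_between": dfb, "df_within": dfw,
                  "error_mean_square": ems, "p": p},
        "duncan": duncan,
    }
    if config.out_dir:
        _write_bundle(bundle, config.out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    bundle["feature_table"].to_csv(os.path.join(out_dir, "features.csv"), index=False)
    bundle["summary"].to_csv(os.path.join(out_dir, "accuracy_summary.csv"), index=False)
    rates = pd.concat(bundle["rates"], names=["classifier", "class"])
    rates.to_csv(os.path.join(out_dir, "rates.csv"))
    pd.DataFrame(bundle["aucs"]).T.rename_axis("classifier").to_csv(
        os.path.join(out_dir, "auc.csv"))
    report = {
        "config_hash": bundle["config_hash"],
        "seed": bundle["config"].seed,
        "anova": bundle["anova"],
        "duncan": None if bundle["duncan"] is None else {
            "names": bundle["duncan"].names,
            "means": bundle["duncan"].means.tolist(),
            "letters": bundle["duncan"].letters,
            "alpha": bundle["duncan"].alpha,
        },
        "accuracies_pct": {k: v.accuracies for k, v in bundle["cv_results"].items()},
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
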