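"""End-to-end orchestration: simulate -> preprocess -> filter -> split -> select -> classify.

``run_pipeline`` executes the stages in the canonical order (baseline +
wavelet denoise + area normalization, then the per-sample RSD outlier
filter, then the 2:1 stratified split, then PCA-loading variable selection
on the calibration set only, then model training and evaluation) and
returns a JSON-serializable run report carrying every count and result the
pipeline produces: shots generated and retained, split sizes, selected
variables with assignments, per-model hyperparameters and accuracies, and
the derived per-stage seeds.  Two runs from the same config and master
seed produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

from . import models as M
from .core import SpectrumSet
from .outliers import OutlierConfig, remove_outliers
from .preprocess import WTConfig, preprocess_set
from .select import SelectionConfig, SelectionResult, select_variables
from .simulate import SimConfig, simulate_dataset

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "variable_reduction_stat",
    "config_from_dict",
]

_MODEL_CONFIGS = {
    "plsda": M.PLSDAConfig,
    "rbfnn": M.RBFNNConfig,
    "svm": M.SVMConfig,
}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    wt: WTConfig = field(default_factory=WTConfig)
    outlier: OutlierConfig = field(default_factory=OutlierConfig)
    split: M.SplitConfig = field(default_factory=M.SplitConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    models: dict[str, Any] = field(
        default_factory=lambda: {name: cfg() for name, cfg in _MODEL_CONFIGS.items()}
    )
    feature_mode: str = "selected"
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_mode not in ("selected", "full_spectrum"):
            raise ValueError("feature_mode must be 'selected' or 'full_spectrum'")
        for name in self.models:
            if name not in _MODEL_CONFIGS:
                raise ValueError(f"unknown model {name!r}")


def variable_reduction_stat(n_full: int, n_selected: int) -> float:
    """Percentage reduction in variable count, rounded to 2 decimals."""
    if not 0 < n_selected <= n_full:
        raise ValueError(
            f"need 0 < n_selected ({n_selected}) <= n_full ({n_full})"
        )
    return round(100.0 * (n_full - n_selected) / n_full, 2)


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    """Derive independent per-stage seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _train(name: str, cfg: Any, X: np.ndarray, y: np.ndarray, seed: int) -> M.TrainedModel:
    if name == "plsda":
        return M.train_plsda(X, y, cfg)
    if name == "rbfnn":
        return M.train_rbfnn(X, y, cfg, random_state=seed)
    return M.train_svm(X, y, cfg, random_state=seed)


def run_pipeline(config: PipelineConfig, data: SpectrumSet | None = None) -> dict[str, Any]:
    """Run the full pipeline; returns the run report dict.

    ``data`` overrides the simulation stage (e.g. spectra loaded from
    disk); otherwise the synthetic dataset is generated from ``config.sim``
    with a seed derived from the master seed.
    """
    seeds = _stage_seeds(config.seed)
    sim_seed, outlier_seed, split_seed, model_seed = seeds[:4]

    if data is None:
        data = simulate_dataset(replace(config.sim, seed=sim_seed))
    n_generated = data.n_shots

    pre = preprocess_set(data, config.wt)
    filtered, outlier_report = remove_outliers(
        pre, replace(config.outlier, seed=outlier_seed), return_report=True
    )

    # ground-truth recovery, when the simulator planted outliers
    truth = [m.is_outlier_truth for m in pre.meta]
    outlier_recall: float | None = None
    if any(t is not None for t in truth):
        kept_ids = {id(m) for m in filtered.meta}
        planted = [i for i, t in enumerate(truth) if t]
        if planted:
            removed_planted = sum(1 for i in planted if id(pre.meta[i]) not in kept_ids)
            outlier_recall = removed_planted / len(planted)

    per_variety = {
        int(v): int((filtered.varieties == v).sum())
        for v in sorted(set(filtered.varieties.tolist()))
    }

    ical, ipred = M.split_indices(filtered, replace(config.split, seed=split_seed))
    assert not set(ical.tolist()) & set(ipred.tolist()), "split sets overlap"
    assert len(ical) + len(ipred) == filtered.n_shots, "split not exhaustive"
    cal, pred = filtered.subset(ical), filtered.subset(ipred)

    selection = select_variables(cal, config.selection, line_table=config.sim.lines)
    sel_idx = selection.indices()

    if config.feature_mode == "selected":
        if sel_idx.size == 0:
            raise RuntimeError("selection stage returned no variables")
        Xc, Xp = cal.intensities[:, sel_idx], pred.intensities[:, sel_idx]
        reduction = variable_reduction_stat(filtered.n_points, sel_idx.size)
    else:
        Xc, Xp = cal.intensities, pred.intensities
        reduction = 0.0
    yc, yp = cal.varieties, pred.varieties

    model_reports: dict[str, Any] = {}
    for name, cfg in config.models.items():
        model = _train(name, cfg, Xc, yc, model_seed)
        report = M.evaluate(model, (Xc, yc), (Xp, yp))
        model_reports[name] = {
            "hyperparameters": {
                k: v for k, v in model.hyperparameters.items()
            },
            "per_class_calibration": [round(float(a), 4) for a in report.per_class_calibration],
            "total_calibration": round(report.total_calibration, 4),
            "per_class_prediction": [round(float(a), 4) for a in report.per_class_prediction],
            "total_prediction": round(report.total_prediction, 4),
        }

    report: dict[str, Any] = {
        "seed": config.seed,
        "stage_seeds": {
            "simulate": sim_seed,
            "outliers": outlier_seed,
            "split": split_seed,
            "models": model_seed,
        },
        "counts": {
            "n_generated": n_generated,
            "n_retained": filtered.n_shots,
            "retained_per_variety": per_variety,
            "n_calibration": int(len(ical)),
            "n_prediction": int(len(ipred)),
            "n_points": int(filtered.n_points),
            "n_selected": int(sel_idx.size),
        },
        "variable_reduction_percent": reduction,
        "outlier_recall": outlier_recall,
        "feature_mode": config.feature_mode,
        "selection": [
            {
                "index": v.index,
                "wavelength_nm": round(v.wavelength_nm, 4),
                "pc": v.pc,
                "loading": round(v.loading, 6),
                "species": v.species,
            }
            for v in selection.variables
        ],
        "models": model_reports,
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        selection.to_frame().to_csv(out / "selection.csv", index=False)
        outlier_report.to_csv(out / "outlier_log.csv", index=False)
    return report


# -- config plumbing (YAML/JSON dicts -> dataclasses) ----------------------


def _build(cls, d: dict[str, Any] | None, **overrides):
    d = dict(d or {})
    d.update(overrides)
    return cls(**d)


def config_from_dict(d: dict[str, Any]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a plain (YAML/JSON) dict.

    Recognized keys: ``preset`` ("paper" or "mini", used as the base
    config), ``sim``, ``wt``, ``outlier``, ``split``, ``selection``,
    ``models`` (mapping model name -> config dict), ``feature_mode``,
    ``output_dir``, ``seed``.
    """
    from . import presets  # local import to avoid a cycle

    d = dict(d)
    preset = d.pop("preset", None)
    if preset is None:
        base = PipelineConfig()
    elif preset == "paper":
        base = presets.paper_like_pipeline_config(seed=d.get("seed", 0))
    elif preset == "mini":
        base = presets.mini_pipeline_config(seed=d.get("seed", 0))
    else:
        raise ValueError(f"unknown preset {preset!r}")

    sim = base.sim
    if "sim" in d:
        sd = dict(d["sim"])
        if "grid" in sd:
            from .core import GridSpec

            sd["grid"] = GridSpec(**sd["grid"])
        if "concentration_matrix" in sd and sd["concentration_matrix"] is not None:
            sd["concentration_matrix"] = np.asarray(sd["concentration_matrix"], dtype=float)
        if "line_table" in sd:
            from .core import read_line_table

            sd["lines"] = read_line_table(sd.pop("line_table"))
        sim = replace(sim, **sd)

    models = dict(base.models)
    if "models" in d:
        models = {}
        for name, md in d["models"].items():
            if name not in _MODEL_CONFIGS:
                raise ValueError(f"unknown model {name!r}")
            base_model = base.models.get(name)
            if md:
                md = {k: tuple(v) if isinstance(v, list) else v for k, v in md.items()}
                models[name] = _MODEL_CONFIGS[name](**md)
            else:
                models[name] = base_model if base_model is not None else _MODEL_CONFIGS[name]()

    return PipelineConfig(
        sim=sim,
        wt=_build(WTConfig, d.get("wt")) if "wt" in d else base.wt,
        outlier=_build(OutlierConfig, d.get("outlier")) if "outlier" in d else base.outlier,
        split=_build(M.SplitConfig, d.get("split")) if "split" in d else base.split,
        selection=_build(SelectionConfig, d.get("selection")) if "selection" in d else base.selection,
        models=models,
        feature_mode=d.get("feature_mode", base.feature_mode),
        output_dir=d.get("output_dir", base.output_dir),
        seed=d.get("seed", base.seed),
    )
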