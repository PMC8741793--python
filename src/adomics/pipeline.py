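"""End-to-end case/control classification experiments.

:class:`ADClassificationModel` is the model object: it binds an aligned
:class:`~adomics.io.MultiOmicsCohort` to an :class:`ExperimentConfig` and
its :meth:`~ADClassificationModel.fit` runs the full training workflow —
mean-impute missing microbiota rows, stratified train/test split, optional
training-set jittering, min-max normalization (jointly over train and test
by default, as the study protocol does, or train-only for a leakage-free
variant), feature selection under one of the four integration strategies,
classifier fitting, and optional probability-threshold tuning. The returned
:class:`ADClassificationResults` carries the selection evidence, the trained
classifier and threshold, exposes :meth:`~ADClassificationResults.evaluate`
on the held-out test set, a :meth:`~ADClassificationResults.summary` table,
and a run log from which the experiment can be replayed bit-identically.

``run_experiment`` / ``run_comparison`` are thin functional wrappers used by
the command-line interface.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from adomics.io import (
    LabelVector,
    MultiOmicsCohort,
    OmicsTable,
    align_modalities,
    read_feature_table,
    read_labels,
)
from adomics.metrics import EvaluationReport
from adomics.models import (
    ClassifierSpec,
    TrainedClassifier,
    classify,
    fit as fit_classifier,
    predict_proba,
    save_model,
    tune_threshold,
)
from adomics.preprocess import (
    JitterSpec,
    SplitIndices,
    add_jitter,
    mean_impute,
    min_max_normalize,
    stratified_split,
)
from adomics.select import (
    STRATEGIES,
    IntegrationResult,
    SelectionConfig,
    integrate,
)
from adomics.simulate import SyntheticConfig, generate_cohort

__all__ = [
    "ExperimentConfig",
    "ADClassificationModel",
    "ADClassificationResults",
    "run_experiment",
    "run_comparison",
    "replay_run",
]

logger = logging.getLogger("adomics")


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, fully seeded.

    Exactly one data source must be given: the three input paths, or a
    synthetic cohort config. ``threshold_grid=None`` keeps the default
    decision threshold p_t = 0.5; otherwise p_t is tuned by stratified-CV
    mean F1 over the grid. ``jitter_stage`` controls whether training noise
    is added to the raw intensities before normalization (the study order)
    or to the normalized block.
    """

    transcriptome_path: Optional[str] = None
    microbiota_path: Optional[str] = None
    labels_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    test_size: int = 30
    seed: int = 0
    normalization_scope: str = "joint"
    strategy: str = "transcriptome_only"
    transcriptome_selection: Optional[SelectionConfig] = None
    microbiota_selection: Optional[SelectionConfig] = None
    combined_selection: Optional[SelectionConfig] = None
    model: ClassifierSpec = field(
        default_factory=lambda: ClassifierSpec("svm_rbf", {}, seed=0)
    )
    jitter: Optional[JitterSpec] = None
    jitter_stage: str = "pre_normalization"
    threshold_grid: Optional[list[float]] = None
    threshold_folds: int = 5
    label: str = ""

    def __post_init__(self) -> None:
        paths = (self.transcriptome_path, self.microbiota_path, self.labels_path)
        has_paths = all(p is not None for p in paths)
        if any(p is not None for p in paths) and not has_paths:
            raise ValueError(
                "transcriptome_path, microbiota_path and labels_path must be "
                "given together"
            )
        if has_paths == (self.synthetic is not None):
            raise ValueError(
                "exactly one of {input paths, synthetic config} must be given"
            )
        if has_paths:
            for key, p in zip(
                ("transcriptome_path", "microbiota_path", "labels_path"), paths
            ):
                if not Path(p).exists():
                    raise FileNotFoundError(f"{key}: no such file {p!r}")
        if self.normalization_scope not in ("joint", "train_only"):
            raise ValueError(
                f"normalization_scope: unknown value {self.normalization_scope!r}"
            )
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy: unknown value {self.strategy!r}")
        if self.jitter_stage not in ("pre_normalization", "post_normalization"):
            raise ValueError(f"jitter_stage: unknown value {self.jitter_stage!r}")
        if self.test_size < 1:
            raise ValueError("test_size must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "transcriptome_path": self.transcriptome_path,
            "microbiota_path": self.microbiota_path,
            "labels_path": self.labels_path,
            "synthetic": asdict(self.synthetic) if self.synthetic else None,
            "test_size": self.test_size,
            "seed": self.seed,
            "normalization_scope": self.normalization_scope,
            "strategy": self.strategy,
            "model": self.model.to_dict(),
            "jitter": asdict(self.jitter) if self.jitter else None,
            "jitter_stage": self.jitter_stage,
            "threshold_grid": self.threshold_grid,
            "threshold_folds": self.threshold_folds,
            "label": self.label,
        }
        for key in (
            "transcriptome_selection",
            "microbiota_selection",
            "combined_selection",
        ):
            cfg = getattr(self, key)
            if cfg is None:
                d[key] = None
            else:
                cd = asdict(cfg)
                cd["model"] = cfg.model.to_dict() if cfg.model else None
                d[key] = cd
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if d.get("jitter"):
            d["jitter"] = JitterSpec(**d["jitter"])
        if d.get("model"):
            d["model"] = ClassifierSpec(**d["model"])
        for key in (
            "transcriptome_selection",
            "microbiota_selection",
            "combined_selection",
        ):
            if d.get(key):
                sd = dict(d[key])
                if sd.get("model"):
                    sd["model"] = ClassifierSpec(**sd["model"])
                d[key] = SelectionConfig(**sd)
        return cls(**d)


def _load_cohort(config: ExperimentConfig) -> MultiOmicsCohort:
    if config.synthetic is not None:
        t, m, y, _truth = generate_cohort(config.synthetic)
    else:
        t = read_feature_table(config.transcriptome_path, "transcriptome")
        m = read_feature_table(config.microbiota_path, "microbiota")
        y = read_labels(config.labels_path)
    return align_modalities(t, m, y)


class ADClassificationModel:
    """A case/control classification experiment bound to one cohort.

    Parameters
    ----------
    cohort : MultiOmicsCohort
        Aligned transcriptome + microbiota tables with labels.
    config : ExperimentConfig
        The full experiment description (split, normalization, selection,
        model, jitter, thresholding).
    """

    def __init__(self, cohort: MultiOmicsCohort, config: ExperimentConfig):
        self.cohort = cohort
        self.config = config

    @classmethod
    def from_tables(
        cls,
        transcriptome: OmicsTable,
        microbiota: OmicsTable,
        labels: LabelVector,
        config: ExperimentConfig,
    ) -> "ADClassificationModel":
        return cls(align_modalities(transcriptome, microbiota, labels), config)

    @classmethod
    def from_config(cls, config: ExperimentConfig) -> "ADClassificationModel":
        """Build the cohort from the config's files or synthetic generator."""
        return cls(_load_cohort(config), config)

    def fit(self) -> "ADClassificationResults":
        """Run the training workflow; test rows are only ever touched by the
        joint normalization (when that mode is on) until evaluation."""
        cfg = self.config
        t0 = time.perf_counter()

        micro = mean_impute(
            self.cohort.microbiota, self.cohort.imputed_microbiota_samples
        )
        logger.info(
            "impute: %d microbiota rows filled (cohort %d x %d)",
            len(self.cohort.imputed_microbiota_samples),
            micro.n_samples,
            micro.n_features,
        )

        split = stratified_split(self.cohort.labels, cfg.test_size, cfg.seed)
        y_map = self.cohort.labels.as_dict()
        y_train = np.array([y_map[s] for s in split.train_ids])
        y_test = np.array([y_map[s] for s in split.test_ids])
        logger.info(
            "split: train %d / test %d (seed %d)",
            len(split.train_ids),
            len(split.test_ids),
            cfg.seed,
        )

        blocks: dict[str, dict[str, np.ndarray]] = {}
        for name, table in (
            ("transcriptome", self.cohort.transcriptome),
            ("microbiota", micro),
        ):
            tr = table.subset_samples(split.train_ids).values
            te = table.subset_samples(split.test_ids).values
            if (
                name == "transcriptome"
                and cfg.jitter is not None
                and cfg.jitter_stage == "pre_normalization"
            ):
                tr = add_jitter(tr, cfg.jitter)
            if cfg.normalization_scope == "joint":
                stacked = min_max_normalize(np.vstack([tr, te]))
                tr_n, te_n = stacked[: len(tr)], stacked[len(tr) :]
            else:
                tr_n = min_max_normalize(tr)
                te_n = min_max_normalize(te, reference=tr)
            if (
                name == "transcriptome"
                and cfg.jitter is not None
                and cfg.jitter_stage == "post_normalization"
            ):
                tr_n = np.clip(add_jitter(tr_n, cfg.jitter), 0.0, None)
            blocks[name] = {"train": tr_n, "test": te_n}
            logger.info("normalize %s: train %s test %s", name, tr_n.shape, te_n.shape)

        t_train = OmicsTable(
            split.train_ids,
            self.cohort.transcriptome.feature_ids,
            blocks["transcriptome"]["train"],
            "transcriptome",
        )
        m_train = OmicsTable(
            split.train_ids,
            micro.feature_ids,
            blocks["microbiota"]["train"],
            "microbiota",
        )
        integration = integrate(
            t_train,
            m_train,
            y_train,
            cfg.strategy,
            transcriptome_config=cfg.transcriptome_selection,
            microbiota_config=cfg.microbiota_selection,
            combined_config=cfg.combined_selection,
        )
        logger.info(
            "select (%s): %d features retained", cfg.strategy, len(integration.feature_ids)
        )

        classifier = fit_classifier(
            cfg.model, integration.X, y_train, feature_ids=integration.feature_ids
        )
        if cfg.threshold_grid:
            p_t, threshold_trace = tune_threshold(
                cfg.model,
                integration.X,
                y_train,
                cfg.threshold_grid,
                n_folds=cfg.threshold_folds,
                seed=cfg.model.seed,
            )
        else:
            p_t, threshold_trace = 0.5, []
        classifier.threshold = p_t
        logger.info(
            "fit %s: threshold p_t=%.2f (%.2fs elapsed)",
            cfg.model.family,
            p_t,
            time.perf_counter() - t0,
        )

        t_pos = {f: i for i, f in enumerate(self.cohort.transcriptome.feature_ids)}
        m_pos = {f: i for i, f in enumerate(micro.feature_ids)}
        test_cols = []
        for f in integration.feature_ids:
            if integration.provenance[f] == "transcriptome":
                test_cols.append(blocks["transcriptome"]["test"][:, t_pos[f]])
            else:
                test_cols.append(blocks["microbiota"]["test"][:, m_pos[f]])
        X_test = (
            np.column_stack(test_cols)
            if test_cols
            else np.empty((len(split.test_ids), 0))
        )

        return ADClassificationResults(
            model=self,
            split=split,
            integration=integration,
            classifier=classifier,
            threshold_trace=threshold_trace,
            X_train=integration.X,
            y_train=y_train,
            X_test=X_test,
            y_test=y_test,
        )


@dataclass
class ADClassificationResults:
    """Fitted experiment: selection evidence, classifier, held-out data."""

    model: ADClassificationModel
    split: SplitIndices
    integration: IntegrationResult
    classifier: TrainedClassifier
    threshold_trace: list[float]
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray

    @property
    def selected_feature_ids(self) -> list[str]:
        return list(self.integration.feature_ids)

    def evaluate(self) -> EvaluationReport:
        """Metrics, ROC and AUC of the tuned classifier on the test set."""
        proba = predict_proba(self.classifier, self.X_test)
        pred = classify(proba, self.classifier.threshold)
        return EvaluationReport.from_predictions(
            proba,
            pred,
            self.y_test,
            provenance={
                "strategy": self.model.config.strategy,
                "n_features": len(self.integration.feature_ids),
                "model": self.classifier.spec.to_dict(),
                "p_t": self.classifier.threshold,
                "seed": self.model.config.seed,
                "label": self.model.config.label,
            },
        )

    def summary(self) -> str:
        """Plain-text summary of the experiment and its test-set metrics."""
        cfg = self.model.config
        report = self.evaluate()
        n_t = sum(
            1 for f in self.integration.feature_ids
            if self.integration.provenance[f] == "transcriptome"
        )
        n_m = len(self.integration.feature_ids) - n_t
        rows = [
            ("cohort samples", self.model.cohort.n_samples),
            ("train / test", f"{len(self.split.train_ids)} / {len(self.split.test_ids)}"),
            ("strategy", cfg.strategy),
            ("features kept (transcriptome / microbiota)", f"{n_t} / {n_m}"),
            ("model", cfg.model.family),
            ("jitter intensity", cfg.jitter.intensity if cfg.jitter else 0),
            ("probability threshold p_t", self.classifier.threshold),
            ("precision", f"{report.precision:.4f}"),
            ("recall", f"{report.recall:.4f}"),
            ("accuracy", f"{report.accuracy:.4f}"),
            ("F1 score", f"{report.f1:.4f}"),
            ("AUC", f"{report.auc:.4f}"),
        ]
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Atopic dermatitis classification results", "=" * 42]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def run_log(self) -> dict[str, Any]:
        """Everything needed to re-execute this run bit-identically."""
        return {
            "adomics_version": _version(),
            "config": self.model.config.to_dict(),
        }

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write selection TSV, model artifact, report, ROC and run log."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        sel_rows = []
        scores: dict[str, float] = {}
        for res in self.integration.selections.values():
            scores.update(res.scores)
        in_final = set(self.integration.feature_ids)
        all_ids = set(scores) | in_final
        for f in sorted(all_ids):
            sel_rows.append(
                {
                    "feature_id": f,
                    "score": scores.get(f, float("nan")),
                    "modality": self.integration.provenance.get(f, ""),
                    "in_final_set": int(f in in_final),
                }
            )
        sel_path = out_dir / "selection.tsv"
        pd.DataFrame(sel_rows).to_csv(sel_path, sep="\t", index=False)
        paths["selection"] = sel_path

        paths["model"] = save_model(self.classifier, out_dir / "model.pkl")
        report = self.evaluate()
        paths.update(report.write(out_dir))

        split_path = out_dir / "split.tsv"
        split_lines = ["sample_id\tpartition"]
        split_lines += [f"{s}\ttrain" for s in self.split.train_ids]
        split_lines += [f"{s}\ttest" for s in self.split.test_ids]
        split_path.write_text("\n".join(split_lines) + "\n", encoding="utf-8")
        paths["split"] = split_path

        log_path = out_dir / "run_log.json"
        log_path.write_text(
            json.dumps(self.run_log(), indent=2) + "\n", encoding="utf-8"
        )
        paths["run_log"] = log_path
        return paths


def _version() -> str:
    from adomics import __version__

    return __version__


def run_experiment(
    config: ExperimentConfig, out_dir: Optional[str | Path] = None
) -> EvaluationReport:
    """Fit the full pipeline and evaluate on the held-out test set."""
    results = ADClassificationModel.from_config(config).fit()
    if out_dir is not None:
        results.save(out_dir)
    return results.evaluate()


def replay_run(log_path: str | Path) -> EvaluationReport:
    """Re-execute a saved run from its log alone."""
    log = json.loads(Path(log_path).read_text(encoding="utf-8"))
    return run_experiment(ExperimentConfig.from_dict(log["config"]))


def run_comparison(configs: list[ExperimentConfig]) -> pd.DataFrame:
    """Evaluate several configs sharing one split; one metrics row each.

    All configs must agree on the split seed and test size — otherwise the
    rows would not be comparable — and the returned frame has the layout of
    a method-comparison table (label, F1, accuracy, precision, recall).
    """
    if len(configs) < 2:
        raise ValueError("a comparison needs at least two configs")
    seeds = {(c.seed, c.test_size) for c in configs}
    if len(seeds) > 1:
        raise ValueError(
            "configs must share the split seed and test size for a valid comparison"
        )
    rows = []
    for i, cfg in enumerate(configs):
        report = run_experiment(cfg)
        rows.append(
            {
                "method": cfg.label or f"config_{i}",
                "f1": report.f1,
                "accuracy": report.accuracy,
                "precision": report.precision,
                "recall": report.recall,
            }
        )
    return pd.DataFrame(rows)
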