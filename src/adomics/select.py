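"""Cross-validated feature selection for high-dimensional omics classifiers.

Three ranker families are provided, one from each classical feature-selection
school:

* a **filter** — the chi-square scorer, computed directly from its matrix
  form: with the binary label vector expanded to a one-hot matrix ``Y`` of
  shape (n, 2),

  .. math::

      f_{obs} = Y^T X, \\qquad
      f_{exp} = \\text{class\\_prob}^T \\cdot \\text{feature\\_count}, \\qquad
      \\chi^2 = \\sum_{classes} (f_{obs} - f_{exp})^2 / f_{exp}

  where ``feature_count`` is the per-feature column sum of X and
  ``class_prob`` the per-class mean of Y. Larger scores mean the feature's
  mass is more unevenly split between cases and controls. Requires
  non-negative input (min-max normalize first).

* a **wrapper** — recursive feature elimination (RFE) over a linear model
  (logistic regression, linear SVM) or a forest, dropping the lowest-weight
  10% of surviving features per refit until one remains.

* an **embedded** method — impurity importances of a seeded random forest.

Two cross-validated plans choose how many features to keep. Both search the
geometric k-schedule (all features, shrinking 10% per step down to 1).
Plan B runs a single stratified five-fold CV on the training set: per fold,
rank on the fold's training split, and score each candidate k by validation
F1; the k with the best mean F1 wins and the final set is the top k of the
full-training ranking. Plan A nests that search inside an outer five-fold
CV — each outer training split gets its own inner-CV-chosen k and feature
set, and the final set is the intersection across outer folds.

All ranking ties are broken lexicographically by feature ID and every fold
split is seeded, so selection is deterministic; no operation ever sees rows
outside the training partition it is handed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from adomics.io import OmicsTable
from adomics.metrics import confusion, metrics
from adomics.models import ClassifierSpec, classify, fit, predict_proba

__all__ = [
    "FeatureRanking",
    "SelectionResult",
    "SelectionConfig",
    "IntegrationResult",
    "chi2_scores",
    "rfe_rank",
    "rfc_importance_rank",
    "rank_features",
    "k_schedule",
    "select_plan_a",
    "select_plan_b",
    "select_features",
    "threshold_select",
    "integrate",
]

RANKERS = ("chi2", "rfe_lr", "rfe_svm", "rfe_rfc", "rfc_importance")
STRATEGIES = (
    "microbiota_only",
    "transcriptome_only",
    "combine_then_select",
    "select_then_combine",
)


@dataclass
class FeatureRanking:
    """Features ordered best-first with parallel non-negative scores."""

    feature_ids: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.feature_ids) != len(self.scores):
            raise ValueError("feature_ids and scores must be parallel")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.feature_ids[:k]


@dataclass
class SelectionResult:
    """A chosen feature subset plus the CV evidence that chose its size.

    ``selected_order`` preserves a deterministic (rank) order for building
    matrices; ``selected_ids`` is the same content as a set. For Plan A,
    ``per_fold_sets`` holds one set per outer fold and ``selected_ids`` is
    their intersection (or, when the intersection is empty, the flagged
    majority fallback). ``cv_trace`` is mean validation F1 per candidate k,
    parallel to ``schedule``.
    """

    selected_ids: set[str]
    selected_order: list[str]
    plan: str
    chosen_k: int
    schedule: list[int] = field(default_factory=list)
    cv_trace: list[float] = field(default_factory=list)
    per_fold_sets: list[set[str]] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)
    fallback_used: bool = False


def _ordered(
    scores: np.ndarray, feature_ids: Sequence[str]
) -> tuple[list[str], np.ndarray]:
    """Order best-first by score, ties broken by feature ID lexicographically."""
    ids = np.asarray(feature_ids, dtype=object)
    order = np.lexsort((ids.astype(str), -np.asarray(scores, dtype=float)))
    return [str(ids[i]) for i in order], np.asarray(scores, dtype=float)[order]


def chi2_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Chi-square independence score of each feature against the labels.

    Computed from the matrix form above; equivalent to the textbook
    two-class chi-square statistic on the (class x feature-mass) contingency
    table. Features with zero total mass score 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_features)")
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    if np.any(X < 0):
        raise ValueError("chi-square scores require non-negative input")
    if len(np.unique(y)) < 2:
        raise ValueError("chi-square scores require both classes present")

    Y = np.column_stack([1 - y, y]).astype(float)  # one-hot: (n, 2)
    f_obs = Y.T @ X  # (2, p)
    feature_count = X.sum(axis=0)  # (p,)
    class_prob = Y.mean(axis=0)  # (2,)
    f_exp = np.outer(class_prob, feature_count)  # (2, p)

    scores = np.zeros(X.shape[1])
    nz = feature_count > 0
    scores[nz] = (((f_obs - f_exp) ** 2)[:, nz] / f_exp[:, nz]).sum(axis=0)
    return scores


def _base_weights(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    model = fit(spec, X, y)
    est = model.estimator
    if hasattr(est, "coef_"):
        return np.abs(np.asarray(est.coef_)).ravel()
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    raise ValueError(
        f"model family {spec.family!r} exposes no per-feature weights; "
        "use a linear kernel or a tree model for RFE"
    )


def rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    base_model: ClassifierSpec,
    step_fraction: float = 0.1,
) -> FeatureRanking:
    """Recursive feature elimination ranking.

    Refits ``base_model`` on the surviving features, drops the lowest-weight
    ``step_fraction`` of them (at least one), and repeats until a single
    feature remains; the ranking is the reverse elimination order. Weight
    ties are broken so the lexicographically smaller feature ID survives
    longer.
    """
    if not 0 < step_fraction < 1:
        raise ValueError("step_fraction must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    ids = [str(f) for f in feature_ids]
    remaining = list(range(len(ids)))
    eliminated: list[int] = []
    while len(remaining) > 1:
        w = _base_weights(base_model, X[:, remaining], y)
        n_drop = min(
            max(1, int(np.floor(step_fraction * len(remaining)))),
            len(remaining) - 1,
        )
        # worst first: ascending weight, lexicographically greater ID first on ties
        keys = np.lexsort(
            (
                np.array([ids[j] for j in remaining], dtype=str),
                np.array([w[i] for i in range(len(remaining))]),
            )
        )
        # among equal weights lexsort puts smaller IDs first; we want to drop
        # greater IDs first, so walk each weight-tie group in reverse
        w_sorted = np.array([w[i] for i in keys])
        drop_order: list[int] = []
        i = 0
        while i < len(keys):
            j = i
            while j + 1 < len(keys) and w_sorted[j + 1] == w_sorted[i]:
                j += 1
            drop_order.extend(reversed(keys[i : j + 1].tolist()))
            i = j + 1
        for local in drop_order[:n_drop]:
            eliminated.append(remaining[local])
        dropped = {remaining[local] for local in drop_order[:n_drop]}
        remaining = [r for r in remaining if r not in dropped]
    eliminated.extend(remaining)
    best_first = [ids[i] for i in reversed(eliminated)]
    scores = np.arange(len(ids), 0, -1, dtype=float)
    return FeatureRanking(best_first, scores, f"rfe_{base_model.family}")


def rfc_importance_rank(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
) -> FeatureRanking:
    """Impurity-based random-forest importances, deterministic under seed."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    spec = ClassifierSpec(
        "random_forest", {"n_estimators": int(n_trees)}, seed=seed
    )
    model = fit(spec, np.asarray(X, dtype=float), y)
    importances = np.asarray(model.estimator.feature_importances_, dtype=float)
    order_ids, order_scores = _ordered(importances, feature_ids)
    return FeatureRanking(order_ids, order_scores, "rfc_importance")


_RFE_BASES = {
    "rfe_lr": "logistic_regression",
    "rfe_svm": "svm_linear",
    "rfe_rfc": "random_forest",
}


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    method: str,
    seed: int = 0,
    step_fraction: float = 0.1,
) -> FeatureRanking:
    """Dispatch to one ranker by method tag (see :data:`RANKERS`)."""
    if method == "chi2":
        scores = chi2_scores(X, y)
        ids, ordered_scores = _ordered(scores, feature_ids)
        return FeatureRanking(ids, ordered_scores, "chi2")
    if method in _RFE_BASES:
        base = ClassifierSpec(_RFE_BASES[method], {}, seed=seed)
        return rfe_rank(X, y, feature_ids, base, step_fraction)
    if method == "rfc_importance":
        return rfc_importance_rank(X, y, feature_ids, seed=seed)
    raise ValueError(f"unknown ranker {method!r}; expected one of {RANKERS}")


def k_schedule(p_total: int) -> list[int]:
    """Candidate feature counts: p_total shrinking 10% per step down to 1.

    Each next value is ``max(1, floor(0.9 * k))``; duplicates are dropped so
    the sequence is strictly decreasing and finite.
    """
    if p_total < 1:
        raise ValueError("p_total must be >= 1")
    ks = [p_total]
    while ks[-1] > 1:
        nxt = max(1, int(np.floor(0.9 * ks[-1])))
        if nxt == ks[-1]:
            nxt -= 1
        ks.append(nxt)
    return ks


def _fold_f1(
    model_spec: ClassifierSpec,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_va: np.ndarray,
    y_va: np.ndarray,
) -> float:
    trained = fit(model_spec, X_tr, y_tr)
    pred = classify(predict_proba(trained, X_va), 0.5)
    return metrics(confusion(pred, y_va)).f1


def _cv_k_search(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    ranker: str,
    n_folds: int,
    schedule: Sequence[int],
    model_spec: ClassifierSpec,
    seed: int,
) -> tuple[int, list[float]]:
    """Mean validation F1 per candidate k; returns (best k, trace).

    Per fold the ranking is computed once on the fold's training split and
    reused for every k. Ties in mean F1 go to the smallest k (parsimony).
    """
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    id_pos = {f: i for i, f in enumerate(feature_ids)}
    fold_scores = np.zeros((n_folds, len(schedule)))
    for fi, (tr, va) in enumerate(skf.split(X, y)):
        ranking = rank_features(X[tr], y[tr], feature_ids, ranker, seed=seed)
        for ki, k in enumerate(schedule):
            cols = [id_pos[f] for f in ranking.top(k)]
            fold_scores[fi, ki] = _fold_f1(
                model_spec, X[np.ix_(tr, cols)], y[tr], X[np.ix_(va, cols)], y[va]
            )
    trace = fold_scores.mean(axis=0)
    best = min(
        (k for i, k in enumerate(schedule) if trace[i] == trace.max()),
        default=schedule[0],
    )
    return int(best), [float(v) for v in trace]


def select_plan_b(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    ranker: str = "chi2",
    n_folds: int = 5,
    schedule: Optional[Sequence[int]] = None,
    model_spec: Optional[ClassifierSpec] = None,
    seed: int = 0,
) -> SelectionResult:
    """Single five-fold CV k-search, then top-k of the full-training ranking."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    schedule = list(schedule) if schedule is not None else k_schedule(X.shape[1])
    model_spec = model_spec or ClassifierSpec("svm_rbf", {}, seed=seed)
    chosen_k, trace = _cv_k_search(
        X, y, feature_ids, ranker, n_folds, schedule, model_spec, seed
    )
    ranking = rank_features(X, y, feature_ids, ranker, seed=seed)
    selected = ranking.top(chosen_k)
    return SelectionResult(
        selected_ids=set(selected),
        selected_order=selected,
        plan="B",
        chosen_k=chosen_k,
        schedule=schedule,
        cv_trace=trace,
        scores=dict(zip(ranking.feature_ids, ranking.scores.tolist())),
    )


def select_plan_a(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    ranker: str = "chi2",
    n_outer: int = 5,
    n_inner: int = 5,
    schedule: Optional[Sequence[int]] = None,
    model_spec: Optional[ClassifierSpec] = None,
    seed: int = 0,
) -> SelectionResult:
    """Nested-CV selection: per-outer-fold inner k-search, then intersect.

    Each outer training split runs the inner-CV k-search, ranks its own rows
    with the chosen k, and contributes one feature set; the final set is the
    intersection. An empty intersection falls back (with a warning and
    ``fallback_used=True``) to features present in at least ``n_outer - 1``
    of the per-fold sets.
    """
    if n_outer < 2 or n_inner < 2:
        raise ValueError("n_outer and n_inner must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    schedule = list(schedule) if schedule is not None else k_schedule(X.shape[1])
    model_spec = model_spec or ClassifierSpec("svm_rbf", {}, seed=seed)
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    per_fold_sets: list[set[str]] = []
    traces = []
    for tr, _va in outer.split(X, y):
        k_opt, trace = _cv_k_search(
            X[tr], y[tr], feature_ids, ranker, n_inner, schedule, model_spec, seed
        )
        ranking = rank_features(X[tr], y[tr], feature_ids, ranker, seed=seed)
        per_fold_sets.append(set(ranking.top(k_opt)))
        traces.append(trace)
    selected = set.intersection(*per_fold_sets)
    fallback = False
    if not selected:
        warnings.warn(
            "empty intersection across outer folds; falling back to features "
            f"present in >= {n_outer - 1} of {n_outer} per-fold sets",
            stacklevel=2,
        )
        fallback = True
        counts: dict[str, int] = {}
        for s in per_fold_sets:
            for f in s:
                counts[f] = counts.get(f, 0) + 1
        selected = {f for f, c in counts.items() if c >= n_outer - 1}
    full_ranking = rank_features(X, y, feature_ids, ranker, seed=seed)
    order = [f for f in full_ranking.feature_ids if f in selected]
    mean_trace = np.mean(traces, axis=0).tolist() if traces else []
    return SelectionResult(
        selected_ids=selected,
        selected_order=order,
        plan="A",
        chosen_k=len(selected),
        schedule=schedule,
        cv_trace=[float(v) for v in mean_trace],
        per_fold_sets=per_fold_sets,
        scores=dict(zip(full_ranking.feature_ids, full_ranking.scores.tolist())),
        fallback_used=fallback,
    )


def threshold_select(ranking: FeatureRanking, importance_floor: float) -> set[str]:
    """Features whose max-rescaled score reaches ``importance_floor``.

    Scores are divided by their maximum so the best feature scores 1; the
    floor is applied to that [0, 1] scale (e.g. a floor of 0.95 keeps only
    near-top features). All-zero scores yield an empty set with a warning.
    """
    scores = np.asarray(ranking.scores, dtype=float)
    top = scores.max(initial=0.0)
    if top <= 0:
        warnings.warn("all feature scores are zero; selecting nothing", stacklevel=2)
        return set()
    rescaled = scores / top
    return {f for f, s in zip(ranking.feature_ids, rescaled) if s >= importance_floor}


@dataclass
class SelectionConfig:
    """How to select features within one modality (or the combined table).

    ``n_features`` set → take the top n of the full-training ranking
    directly (the fixed-size mode used for the 35-probe / 50-taxon sets);
    ``importance_floor`` set → threshold on max-rescaled scores; otherwise
    the plan's cross-validated k-search runs over ``schedule`` (default:
    the full 10%-shrink schedule).
    """

    plan: str = "B"
    ranker: str = "chi2"
    n_folds: int = 5
    n_outer: int = 5
    schedule: Optional[list[int]] = None
    n_features: Optional[int] = None
    importance_floor: Optional[float] = None
    model: Optional[ClassifierSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plan not in ("A", "B"):
            raise ValueError(f"plan must be 'A' or 'B', got {self.plan!r}")
        if self.ranker not in RANKERS:
            raise ValueError(f"unknown ranker {self.ranker!r}")


def select_features(
    X: np.ndarray, y: np.ndarray, feature_ids: Sequence[str], cfg: SelectionConfig
) -> SelectionResult:
    """Run the selection mode described by ``cfg`` on a training matrix."""
    X = np.asarray(X, dtype=float)
    if cfg.n_features is not None:
        ranking = rank_features(X, y, feature_ids, cfg.ranker, seed=cfg.seed)
        selected = ranking.top(cfg.n_features)
        return SelectionResult(
            selected_ids=set(selected),
            selected_order=selected,
            plan=cfg.plan,
            chosen_k=cfg.n_features,
            scores=dict(zip(ranking.feature_ids, ranking.scores.tolist())),
        )
    if cfg.importance_floor is not None:
        ranking = rank_features(X, y, feature_ids, cfg.ranker, seed=cfg.seed)
        chosen = threshold_select(ranking, cfg.importance_floor)
        order = [f for f in ranking.feature_ids if f in chosen]
        return SelectionResult(
            selected_ids=chosen,
            selected_order=order,
            plan=cfg.plan,
            chosen_k=len(chosen),
            scores=dict(zip(ranking.feature_ids, ranking.scores.tolist())),
        )
    if cfg.plan == "B":
        return select_plan_b(
            X,
            y,
            feature_ids,
            ranker=cfg.ranker,
            n_folds=cfg.n_folds,
            schedule=cfg.schedule,
            model_spec=cfg.model,
            seed=cfg.seed,
        )
    return select_plan_a(
        X,
        y,
        feature_ids,
        ranker=cfg.ranker,
        n_outer=cfg.n_outer,
        n_inner=cfg.n_folds,
        schedule=cfg.schedule,
        model_spec=cfg.model,
        seed=cfg.seed,
    )


@dataclass
class IntegrationResult:
    """A combined training matrix with per-feature modality provenance."""

    X: np.ndarray
    feature_ids: list[str]
    provenance: dict[str, str]  # feature_id -> modality
    selections: dict[str, SelectionResult] = field(default_factory=dict)


def integrate(
    t_table: OmicsTable,
    m_table: OmicsTable,
    y: np.ndarray,
    strategy: str,
    transcriptome_config: Optional[SelectionConfig] = None,
    microbiota_config: Optional[SelectionConfig] = None,
    combined_config: Optional[SelectionConfig] = None,
) -> IntegrationResult:
    """Build the model's input matrix under one of four fusion strategies.

    1. ``microbiota_only`` / 2. ``transcriptome_only`` — single modality,
       selected with its config (``None`` disables selection and keeps all
       features);
    3. ``combine_then_select`` — concatenate the modality columns first,
       then run one selection on the combined table;
    4. ``select_then_combine`` — select within each modality, then
       concatenate the selected columns (transcriptome first).

    Both tables must already be aligned to the same sample order. Only
    training rows should be passed; the returned feature list is then used
    to slice test rows.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if t_table.sample_ids != m_table.sample_ids:
        raise ValueError("modalities must share an identical sample order")
    overlap = set(t_table.feature_ids) & set(m_table.feature_ids)
    if overlap:
        raise ValueError(
            f"feature IDs shared across modalities: {sorted(overlap)[:5]}"
        )

    def one(table: OmicsTable, cfg: Optional[SelectionConfig], modality: str):
        if cfg is None:
            ids = list(table.feature_ids)
            return table.values, ids, None
        res = select_features(table.values, y, table.feature_ids, cfg)
        pos = {f: i for i, f in enumerate(table.feature_ids)}
        ids = list(res.selected_order)
        return table.values[:, [pos[f] for f in ids]], ids, res

    if strategy == "microbiota_only":
        Xm, ids, res = one(m_table, microbiota_config, "microbiota")
        return IntegrationResult(
            Xm, ids, {f: "microbiota" for f in ids},
            {"microbiota": res} if res else {},
        )
    if strategy == "transcriptome_only":
        Xt, ids, res = one(t_table, transcriptome_config, "transcriptome")
        return IntegrationResult(
            Xt, ids, {f: "transcriptome" for f in ids},
            {"transcriptome": res} if res else {},
        )
    if strategy == "combine_then_select":
        X = np.hstack([t_table.values, m_table.values])
        ids = list(t_table.feature_ids) + list(m_table.feature_ids)
        prov = {f: "transcriptome" for f in t_table.feature_ids}
        prov.update({f: "microbiota" for f in m_table.feature_ids})
        if combined_config is None:
            return IntegrationResult(X, ids, prov, {})
        res = select_features(X, y, ids, combined_config)
        pos = {f: i for i, f in enumerate(ids)}
        kept = list(res.selected_order)
        return IntegrationResult(
            X[:, [pos[f] for f in kept]],
            kept,
            {f: prov[f] for f in kept},
            {"combined": res},
        )
    # select_then_combine
    Xt, t_ids, t_res = one(t_table, transcriptome_config, "transcriptome")
    Xm, m_ids, m_res = one(m_table, microbiota_config, "microbiota")
    prov = {f: "transcriptome" for f in t_ids}
    prov.update({f: "microbiota" for f in m_ids})
    selections = {}
    if t_res:
        selections["transcriptome"] = t_res
    if m_res:
        selections["microbiota"] = m_res
    return IntegrationResult(np.hstack([Xt, Xm]), t_ids + m_ids, prov, selections)
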