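"""Imputation, stratified splitting, min-max normalization, and jittering.

The preprocessing order follows the study protocol: mean-impute the missing
microbiota rows first, split into stratified training/test sets, then
min-max normalize each feature to [0, 1] (by default over training and test
jointly, as the protocol does; a train-only mode that fits the scaler on
the training rows alone is available for leakage-free workflows). Jittering
— additive Gaussian noise on the normalized training transcriptome block —
is a regularizer against overfitting and is never applied to the
zero-heavy microbiota block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from adomics.io import LabelVector, OmicsTable

__all__ = [
    "SplitIndices",
    "JitterSpec",
    "stratified_split",
    "min_max_normalize",
    "mean_impute",
    "add_jitter",
]


@dataclass
class SplitIndices:
    """A stratified train/test partition of a cohort's sample IDs."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sample IDs overlap")


@dataclass
class JitterSpec:
    """Additive Gaussian training noise s ~ N(0, sigma^2 I).

    ``intensity`` is the noise scale I applied to normalized data. With the
    default ``variance_convention="variance_equals_I"`` the noise variance is
    I (standard deviation sqrt(I)); ``"sd_equals_I"`` reads I as the standard
    deviation instead — the product notation admits both readings.
    """

    intensity: float
    seed: int = 0
    variance_convention: str = "variance_equals_I"

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"jitter intensity must be >= 0, got {self.intensity}")
        if self.variance_convention not in ("variance_equals_I", "sd_equals_I"):
            raise ValueError(
                f"unknown variance_convention {self.variance_convention!r}"
            )

    @property
    def sd(self) -> float:
        if self.variance_convention == "variance_equals_I":
            return float(np.sqrt(self.intensity))
        return float(self.intensity)


def stratified_split(y: LabelVector, test_size: int, seed: int) -> SplitIndices:
    """Deterministic stratified split preserving the case:control balance.

    The test set receives ``round(test_size * class_count / n)`` samples of
    each class, allocated by the largest-remainder rule so the test size is
    hit exactly. For the study cohort (88 cases, 73 controls, test_size=30)
    this gives a 131/30 split with 16 cases and 14 controls held out.
    """
    n = len(y)
    if not 0 < test_size < n:
        raise ValueError(f"test_size must be in (0, {n}), got {test_size}")
    classes = np.unique(y.labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")

    quotas = {c: test_size * int((y.labels == c).sum()) / n for c in classes}
    take = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = test_size - sum(take.values())
    # largest remainder; ties broken by class value for determinism
    for c in sorted(classes, key=lambda c: (-(quotas[c] - take[c]), c))[:short]:
        take[c] += 1
    for c in classes:
        if take[c] == 0:
            warnings.warn(
                f"class {c} would receive 0 test samples; forcing 1", stacklevel=2
            )
            take[c] = 1
            donor = max(take, key=lambda k: take[k])
            take[donor] -= 1

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(y.labels == c)
        test_idx.extend(rng.choice(members, size=take[c], replace=False))
    test_set = set(test_idx)
    train_ids = [s for i, s in enumerate(y.sample_ids) if i not in test_set]
    test_ids = [s for i, s in enumerate(y.sample_ids) if i in test_set]
    return SplitIndices(train_ids, test_ids, seed)


def min_max_normalize(
    values: np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """Per-feature linear rescaling x' = (x - min(x)) / (max(x) - min(x)).

    Column minima and maxima are taken from ``reference`` when given (the
    training block, for leakage-free normalization) and from ``values``
    itself otherwise. Constant columns map to 0 everywhere — the formula's
    denominator vanishes, and 0 keeps the output non-negative for the
    chi-square scorer. Idempotent on its own output.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("min-max normalization requires finite input")
    ref = values if reference is None else np.asarray(reference, dtype=float)
    if not np.all(np.isfinite(ref)):
        raise ValueError("min-max normalization requires finite reference")
    lo = ref.min(axis=0)
    span = ref.max(axis=0) - lo
    out = np.zeros_like(values)
    nz = span > 0
    out[:, nz] = (values[:, nz] - lo[nz]) / span[nz]
    if reference is not None:
        out = np.clip(out, 0.0, 1.0)
    return out


def mean_impute(table: OmicsTable, missing_samples: set[str]) -> OmicsTable:
    """Replace each flagged sample's row with per-feature means.

    Means are computed over the non-flagged rows only; this is mean-value
    imputation under the missing-completely-at-random assumption.
    """
    unknown = set(missing_samples) - set(table.sample_ids)
    if unknown:
        raise KeyError(f"flagged samples not in table: {sorted(unknown)[:5]}")
    if not missing_samples:
        return table
    flags = np.array([s in missing_samples for s in table.sample_ids])
    if flags.all():
        raise ValueError("cannot impute: every sample is flagged missing")
    values = table.values.copy()
    values[flags] = table.values[~flags].mean(axis=0)
    return OmicsTable(
        list(table.sample_ids), list(table.feature_ids), values, table.modality
    )


def add_jitter(values: np.ndarray, spec: JitterSpec) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise to a normalized training block.

    Deterministic under ``spec.seed``; ``intensity=0`` returns the input
    unchanged. Apply only to the transcriptome training block — microbiota
    abundances are mostly zeros that noise would distort.
    """
    values = np.asarray(values, dtype=float)
    if spec.intensity == 0:
        return values.copy()
    rng = np.random.default_rng(spec.seed)
    return values + rng.normal(0.0, spec.sd, size=values.shape)
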