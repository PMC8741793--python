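"""Feature-table I/O and modality alignment.

One cohort carries two sample-by-feature tables — a transcriptome table of
continuous probe intensities and a microbiota table of non-negative relative
abundances — plus a binary case/control label vector. Alignment follows the
keep/impute/drop rule used for the study cohort: every sample with
transcriptome data and a label is kept; a kept sample lacking a microbiota
row gets a placeholder row (filled later by mean imputation, see
:func:`adomics.preprocess.mean_impute`); a sample with only microbiota data
is dropped, since imputing tens of thousands of probes is not sensible.

All tables are tab-separated UTF-8 text with '.' decimals: first row
= feature IDs, first column = sample IDs. Files stored features-as-rows are
supported via ``orientation="features_as_rows"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OmicsTable",
    "LabelVector",
    "MultiOmicsCohort",
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_labels",
    "align_modalities",
]

MODALITIES = ("transcriptome", "microbiota")


class FeatureTableError(ValueError):
    """Malformed feature table or label file."""


@dataclass
class OmicsTable:
    """A sample-by-feature numeric matrix for one omics modality.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (rows).
    feature_ids : list of str
        Ordered, unique feature identifiers (columns): probe IDs for the
        transcriptome, taxon names for the microbiota.
    values : ndarray of shape (n_samples, n_features)
        Probe intensities (arbitrary units) or relative abundances.
    modality : {"transcriptome", "microbiota"}
        Microbiota values must be non-negative.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise FeatureTableError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.values.ndim != 2:
            raise FeatureTableError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise FeatureTableError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.feature_ids)} features)"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise FeatureTableError(f"duplicate {name} identifier {dup!r}")
        if self.modality == "microbiota":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < 0:
                raise FeatureTableError("microbiota abundances must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def subset_samples(self, sample_ids: list[str]) -> "OmicsTable":
        """Rows restricted/reordered to ``sample_ids`` (all must be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return OmicsTable(
            list(sample_ids), list(self.feature_ids), self.values[idx], self.modality
        )


@dataclass
class LabelVector:
    """Binary phenotype per sample: 1 = case (atopic dermatitis), 0 = control."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise FeatureTableError("labels must be a vector parallel to sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FeatureTableError("duplicate sample identifier in labels")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise FeatureTableError(f"labels must be 0/1, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.sample_ids, self.labels.tolist()))

    def subset(self, sample_ids: list[str]) -> "LabelVector":
        d = self.as_dict()
        return LabelVector(list(sample_ids), np.array([d[s] for s in sample_ids]))


@dataclass
class MultiOmicsCohort:
    """Aligned transcriptome + microbiota tables with shared sample order.

    ``imputed_microbiota_samples`` records samples whose microbiota row is a
    placeholder awaiting mean imputation.
    """

    transcriptome: OmicsTable
    microbiota: OmicsTable
    labels: LabelVector
    imputed_microbiota_samples: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = self.transcriptome.sample_ids
        if self.microbiota.sample_ids != ids or self.labels.sample_ids != ids:
            raise FeatureTableError(
                "cohort components must share an identical ordered sample-ID list"
            )
        extra = self.imputed_microbiota_samples - set(ids)
        if extra:
            raise FeatureTableError(f"imputed flags for unknown samples: {sorted(extra)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.transcriptome.sample_ids

    @property
    def n_samples(self) -> int:
        return self.transcriptome.n_samples


def _orient(df: pd.DataFrame, orientation: str) -> pd.DataFrame:
    if orientation == "samples_as_rows":
        return df
    if orientation == "features_as_rows":
        return df.T
    raise FeatureTableError(f"unknown orientation {orientation!r}")


def read_feature_table(
    path: str | Path, modality: str, orientation: str = "samples_as_rows"
) -> OmicsTable:
    """Read a tab-separated feature table.

    First row holds feature IDs, first column sample IDs (swapped under
    ``orientation="features_as_rows"``). Every body cell must parse as a
    number; a non-numeric cell raises :class:`FeatureTableError` naming the
    offending row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df = _orient(df, orientation)
    try:
        numeric = df.astype(float)
    except ValueError:
        for col in df.columns:
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise FeatureTableError(
                    f"{path}: non-numeric cell {df[col][bad].iloc[0]!r} "
                    f"at row {row!r}, column {col!r}"
                ) from None
        raise
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any(axis=0).argmax()]
        row = numeric.index[numeric[col].isna().argmax()]
        raise FeatureTableError(
            f"{path}: missing/NA cell at row {row!r}, column {col!r}"
        )
    return OmicsTable(
        list(numeric.index.astype(str)),
        list(numeric.columns.astype(str)),
        numeric.to_numpy(dtype=float),
        modality,
    )


def write_feature_table(
    table: OmicsTable, path: str | Path, orientation: str = "samples_as_rows"
) -> Path:
    """Write a table as UTF-8 TSV, full float precision, '.' decimal."""
    path = Path(path)
    df = table.to_frame()
    df = _orient(df, orientation) if orientation == "features_as_rows" else df
    df.to_csv(path, sep="\t", float_format="%.17g", encoding="utf-8")
    return path


_LABEL_ALIASES = {"1": 1, "0": 0, "case": 1, "control": 0, "ad": 1}


def read_labels(path: str | Path) -> LabelVector:
    """Read a two-column TSV (sample_id, label).

    Labels may be 0/1 or the strings "case"/"control" (case-insensitive;
    "AD" is accepted as a case synonym).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FeatureTableError(f"{path}: expected two columns (sample_id, label)")
    ids = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1].astype(str).str.strip().str.lower()
    unknown = sorted(set(raw) - set(_LABEL_ALIASES))
    if unknown:
        raise FeatureTableError(f"{path}: unrecognized label values {unknown[:5]}")
    return LabelVector(ids, np.array([_LABEL_ALIASES[v] for v in raw]))


def write_labels(labels: LabelVector, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"sample_id": labels.sample_ids, "label": labels.labels}
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def align_modalities(
    transcriptome: OmicsTable, microbiota: OmicsTable, labels: LabelVector
) -> MultiOmicsCohort:
    """Align the two modalities into one cohort.

    Kept samples are exactly those with a transcriptome row *and* a label,
    in transcriptome order. A kept sample without a microbiota row receives
    a placeholder row of zeros and is recorded in
    ``imputed_microbiota_samples`` (fill it with
    :func:`adomics.preprocess.mean_impute` before analysis). Samples with
    only microbiota data, and unlabeled samples, are dropped. Idempotent on
    an aligned cohort.
    """
    label_map = labels.as_dict()
    kept = [s for s in transcriptome.sample_ids if s in label_map]
    if not kept:
        raise FeatureTableError("no transcriptome sample has a label")
    t = transcriptome.subset_samples(kept)

    micro_pos = {s: i for i, s in enumerate(microbiota.sample_ids)}
    imputed = {s for s in kept if s not in micro_pos}
    m_values = np.zeros((len(kept), microbiota.n_features))
    for i, s in enumerate(kept):
        if s in micro_pos:
            m_values[i] = microbiota.values[micro_pos[s]]
    m = OmicsTable(list(kept), list(microbiota.feature_ids), m_values, "microbiota")
    y = labels.subset(kept)
    return MultiOmicsCohort(t, m, y, imputed)
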