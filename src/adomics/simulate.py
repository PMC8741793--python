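"""Synthetic paired transcriptome/microbiota cohorts with planted signal.

The study cohort (161 children: 88 atopic-dermatitis cases, 73 controls;
44,608 expression probes; 366 phylum/genus taxa; one sample missing each
modality) is not publicly deposited, so this module generates cohorts of
the same shape with known ground truth, letting every pipeline stage be
tested for recovery without any download.

Transcriptome intensities are per-probe log-normal: a Gaussian on log scale,
exponentiated, so min-max normalization is exercised on skewed positive
data. Signal probes shift the case-group log mean by ``probe_effect``
standard deviations (Cohen's d on the log scale). Microbiota rows are drawn
from a per-sample Dirichlet whose concentration for signal taxa is scaled by
``taxa_effect`` in cases, normalized to sum to one, then structurally zeroed
cell-wise with probability ``zero_inflation`` — reproducing the sparsity
that makes additive jitter inappropriate for this modality.

Ground-truth signal feature IDs are returned so tests can measure recovery;
the pipeline itself never reads them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from adomics.io import (
    LabelVector,
    OmicsTable,
    write_feature_table,
    write_labels,
)

__all__ = ["SyntheticConfig", "generate_cohort", "write_fixture"]


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the study cohort's shape: 88 cases / 73 controls,
    44,608 probes, 366 taxa, 35 signal probes and 50 signal taxa (the sizes
    of the selected feature sets), one sample missing from each modality.

    Parameters
    ----------
    probe_effect : float
        Standardized case-vs-control mean shift (Cohen's d, log scale) of
        each signal probe.
    taxa_effect : float
        Case/control ratio of the Dirichlet concentration (hence of mean
        relative abundance, before renormalization) of each signal taxon.
    zero_inflation : float
        Probability that any taxon cell is structurally zero.
    missing_transcriptome : int
        Number of extra microbiota-only samples (labeled, no transcriptome
        row; dropped at alignment).
    missing_microbiota : int
        Number of cohort samples whose microbiota row is absent (imputed at
        alignment).
    """

    n_cases: int = 88
    n_controls: int = 73
    n_probes: int = 44608
    n_taxa: int = 366
    n_signal_probes: int = 35
    n_signal_taxa: int = 50
    probe_effect: float = 1.0
    taxa_effect: float = 3.0
    zero_inflation: float = 0.6
    missing_transcriptome: int = 1
    missing_microbiota: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_probes": self.n_probes,
            "n_taxa": self.n_taxa,
            "n_signal_probes": self.n_signal_probes,
            "n_signal_taxa": self.n_signal_taxa,
            "missing_transcriptome": self.missing_transcriptome,
            "missing_microbiota": self.missing_microbiota,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_signal_probes > self.n_probes:
            raise ValueError("n_signal_probes exceeds n_probes")
        if self.n_signal_taxa > self.n_taxa:
            raise ValueError("n_signal_taxa exceeds n_taxa")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.probe_effect < 0:
            raise ValueError("probe_effect must be >= 0")
        if self.taxa_effect <= 0:
            raise ValueError("taxa_effect must be > 0")
        if self.missing_microbiota > self.n_cases + self.n_controls:
            raise ValueError("missing_microbiota exceeds the cohort size")


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[OmicsTable, OmicsTable, LabelVector, dict[str, list[str]]]:
    """Draw one cohort; identical config + seed gives bit-identical output.

    Returns
    -------
    transcriptome : OmicsTable
        Cohort samples minus the microbiota-only extras.
    microbiota : OmicsTable
        Cohort samples minus ``missing_microbiota`` randomly chosen ones,
        plus the microbiota-only extras.
    labels : LabelVector
        Every sample of either table.
    ground_truth : dict
        ``{"signal_probes": [...], "signal_taxa": [...]}``.
    """
    rng = np.random.default_rng(config.seed)
    n_core = config.n_cases + config.n_controls
    n_extra = config.missing_transcriptome

    core_ids = [f"S{i:04d}" for i in range(n_core)]
    extra_ids = [f"X{i:04d}" for i in range(n_extra)]
    probe_ids = [f"probe_{i:05d}" for i in range(config.n_probes)]
    taxon_ids = [f"taxon_{i:04d}" for i in range(config.n_taxa)]

    y_core = np.array([1] * config.n_cases + [0] * config.n_controls)
    rng.shuffle(y_core)
    # extras get labels too (they are dropped at alignment regardless)
    y_extra = rng.integers(0, 2, size=n_extra)

    signal_probes = list(
        rng.choice(config.n_probes, size=config.n_signal_probes, replace=False)
    )
    signal_taxa = list(
        rng.choice(config.n_taxa, size=config.n_signal_taxa, replace=False)
    )

    # transcriptome: per-probe Gaussian on log scale, exponentiated
    base_mu = rng.normal(5.0, 1.0, size=config.n_probes)
    base_sd = rng.uniform(0.3, 0.8, size=config.n_probes)
    log_x = rng.normal(base_mu, base_sd, size=(n_core, config.n_probes))
    shift = np.zeros(config.n_probes)
    shift[signal_probes] = config.probe_effect * base_sd[signal_probes]
    log_x += np.outer(y_core, shift)
    transcriptome = OmicsTable(
        core_ids, probe_ids, np.exp(log_x), "transcriptome"
    )

    # microbiota: Dirichlet composition, signal taxa concentrated in cases,
    # then Bernoulli structural zeros
    base_conc = rng.gamma(0.8, 1.0, size=config.n_taxa) + 0.05
    conc_case = base_conc.copy()
    conc_case[signal_taxa] *= config.taxa_effect

    micro_drop = set(
        rng.choice(n_core, size=config.missing_microbiota, replace=False)
    ) if config.missing_microbiota else set()

    all_micro_ids: list[str] = []
    micro_rows: list[np.ndarray] = []
    micro_labels: list[int] = []
    for i, sid in enumerate(core_ids):
        conc = conc_case if y_core[i] == 1 else base_conc
        row = rng.dirichlet(conc)
        mask = rng.random(config.n_taxa) < config.zero_inflation
        row = np.where(mask, 0.0, row)
        if i not in micro_drop:
            all_micro_ids.append(sid)
            micro_rows.append(row)
            micro_labels.append(int(y_core[i]))
    for j, sid in enumerate(extra_ids):
        conc = conc_case if y_extra[j] == 1 else base_conc
        row = rng.dirichlet(conc)
        mask = rng.random(config.n_taxa) < config.zero_inflation
        row = np.where(mask, 0.0, row)
        all_micro_ids.append(sid)
        micro_rows.append(row)
    microbiota = OmicsTable(
        all_micro_ids,
        taxon_ids,
        np.vstack(micro_rows) if micro_rows else np.empty((0, config.n_taxa)),
        "microbiota",
    )

    labels = LabelVector(
        core_ids + extra_ids,
        np.concatenate([y_core, y_extra]).astype(int),
    )
    ground_truth = {
        "signal_probes": sorted(probe_ids[i] for i in signal_probes),
        "signal_taxa": sorted(taxon_ids[i] for i in signal_taxa),
    }
    return transcriptome, microbiota, labels, ground_truth


def write_fixture(
    transcriptome: OmicsTable,
    microbiota: OmicsTable,
    labels: LabelVector,
    ground_truth: dict[str, list[str]],
    directory: str | Path,
) -> dict[str, Path]:
    """Write the cohort as the three TSVs plus a ground-truth ID list.

    Files round-trip exactly through :func:`adomics.io.read_feature_table`
    and :func:`adomics.io.read_labels`; byte-identical for identical input.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcriptome": directory / "transcriptome.tsv",
        "microbiota": directory / "microbiota.tsv",
        "labels": directory / "labels.tsv",
        "ground_truth": directory / "ground_truth.tsv",
    }
    write_feature_table(transcriptome, paths["transcriptome"])
    write_feature_table(microbiota, paths["microbiota"])
    write_labels(labels, paths["labels"])
    lines = ["feature_id\tmodality"]
    lines += [f"{fid}\ttranscriptome" for fid in ground_truth["signal_probes"]]
    lines += [f"{fid}\tmicrobiota" for fid in ground_truth["signal_taxa"]]
    paths["ground_truth"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths
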