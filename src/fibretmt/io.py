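"""Core data types and TSV readers/writers for the single-fibre TMT pipeline.

The pipeline's in-memory containers are thin wrappers around pandas objects:

* :class:`QuantMatrix` — a proteins x samples abundance grid (NaN = missing)
  carrying a ``scale`` flag (``"raw"`` reporter intensities or ``"log2"``
  abundances).
* Sample and protein annotations are plain DataFrames validated by
  :func:`validate_sample_annotation` / :func:`validate_protein_annotation`.

Sample identifiers are opaque strings: every piece of design information
(participant, fibre type, timepoint, training group, TMT plex, channel)
lives in the sample annotation and is never parsed out of an id.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

RAW = "raw"
LOG2 = "log2"

FIBRE_TYPES = ("I", "II")
TIMEPOINTS = ("PRE", "POST")
TRAINING_GROUPS = ("MICT", "SIT")

#: Default vocabulary of functional-group labels used in profile analyses.
FUNCTIONAL_GROUPS = (
    "CI",
    "CII",
    "CIII",
    "CIV",
    "CV",
    "MitoRibosome",
    "TCA",
    "FattyAcidOxidation",
    "MitoDynamics",
    "Glycolysis",
    "StriatedContraction",
)

#: Functional groups whose members must carry the mitochondrial flag.
MITO_GROUPS = frozenset(
    {"CI", "CII", "CIII", "CIV", "CV", "MitoRibosome", "TCA",
     "FattyAcidOxidation", "MitoDynamics"}
)

SAMPLE_COLUMNS = (
    "sample_id", "participant_id", "fibre_type", "timepoint",
    "training", "plex_id", "channel_label",
)
PROTEIN_COLUMNS = (
    "protein_id", "gene_symbol", "unique_peptides", "confidence",
    "contaminant", "is_mitochondrial", "functional_groups",
)

MISSING_TOKENS = ("", "NA")


class ParseError(ValueError):
    """A malformed input file (names the offending row/column)."""


class ValidationError(ValueError):
    """A domain invariant violated by otherwise well-formed data."""


# ---------------------------------------------------------------------------
# QuantMatrix


@dataclass
class QuantMatrix:
    """Proteins x samples abundance grid with explicit missing entries.

    Parameters
    ----------
    data:
        DataFrame indexed by protein id with sample ids as columns;
        ``NaN`` marks a missing measurement.
    scale:
        ``"raw"`` for reporter intensities (non-negative where present) or
        ``"log2"`` for log2 abundances.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        dup_p = self.data.index[self.data.index.duplicated()]
        if len(dup_p):
            raise ValidationError(f"duplicate protein id(s): {sorted(set(dup_p))}")
        dup_s = self.data.columns[self.data.columns.duplicated()]
        if len(dup_s):
            raise ValidationError(f"duplicate sample id(s): {sorted(set(dup_s))}")
        if self.scale == RAW:
            vals = self.data.to_numpy()
            neg = np.asarray(vals < 0).nonzero()
            if neg[0].size:
                r, c = neg[0][0], neg[1][0]
                raise ValidationError(
                    "negative raw intensity at protein "
                    f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
                )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "QuantMatrix":
        return QuantMatrix(data, self.scale if scale is None else scale)

    def subset_proteins(self, protein_ids: Iterable[str]) -> "QuantMatrix":
        ids = [p for p in protein_ids]
        unknown = set(ids) - set(self.data.index)
        if unknown:
            raise ValidationError(f"unknown protein id(s): {sorted(unknown)}")
        return QuantMatrix(self.data.loc[ids], self.scale)

    def subset_samples(self, sample_ids: Iterable[str]) -> "QuantMatrix":
        ids = [s for s in sample_ids]
        unknown = set(ids) - set(self.data.columns)
        if unknown:
            raise ValidationError(f"unknown sample id(s): {sorted(unknown)}")
        return QuantMatrix(self.data[ids], self.scale)


def read_quant_matrix(path: str | Path, scale: str) -> QuantMatrix:
    """Read a tab-separated proteins x samples matrix.

    First column holds protein ids, the header row sample ids; empty cells
    and ``NA`` are missing. Duplicate ids and negative raw intensities are
    rejected with errors naming the offender.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: header must contain at least one sample column")
    sample_ids = header[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ParseError(f"{path}: duplicate sample id {s!r} in header")
        seen.add(s)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
        keep_default_na=False, dtype=str,
    )
    df.columns = sample_ids
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric abundance value ({exc})") from exc
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ParseError(f"{path}: duplicate protein id(s) {dup}")
    return QuantMatrix(df, scale)


def write_quant_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with ``NA`` for missing entries.

    Values are written at full precision so a write -> read round trip is
    value-exact.
    """
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="protein_id")


# ---------------------------------------------------------------------------
# Annotations


def validate_sample_annotation(
    annot: pd.DataFrame, matrix: QuantMatrix | None = None
) -> pd.DataFrame:
    """Check sample-annotation invariants, optionally against a matrix.

    Invariants: required columns present; (participant, fibre, timepoint)
    unique; each participant in exactly one training group; fibre/timepoint/
    training codes drawn from the declared vocabularies; when a matrix is
    supplied, its samples and the annotation's samples coincide.
    """
    missing = set(SAMPLE_COLUMNS) - set(annot.columns)
    if missing:
        raise ValidationError(f"sample annotation missing column(s): {sorted(missing)}")
    annot = annot.copy()
    for col in ("sample_id", "participant_id", "fibre_type", "timepoint",
                "training", "plex_id", "channel_label"):
        annot[col] = annot[col].astype(str)
    if annot["sample_id"].duplicated().any():
        dup = sorted(set(annot.loc[annot["sample_id"].duplicated(), "sample_id"]))
        raise ValidationError(f"duplicate sample id(s) in annotation: {dup}")
    bad = set(annot["fibre_type"]) - set(FIBRE_TYPES)
    if bad:
        raise ValidationError(f"unknown fibre type code(s): {sorted(bad)}")
    bad = set(annot["timepoint"]) - set(TIMEPOINTS)
    if bad:
        raise ValidationError(f"unknown timepoint code(s): {sorted(bad)}")
    bad = set(annot["training"]) - set(TRAINING_GROUPS)
    if bad:
        raise ValidationError(f"unknown training code(s): {sorted(bad)}")
    key = annot[["participant_id", "fibre_type", "timepoint"]]
    if key.duplicated().any():
        row = key[key.duplicated()].iloc[0]
        raise ValidationError(
            "duplicate (participant, fibre, timepoint): "
            f"({row.participant_id}, {row.fibre_type}, {row.timepoint})"
        )
    groups = annot.groupby("participant_id")["training"].nunique()
    multi = groups[groups > 1]
    if len(multi):
        raise ValidationError(
            f"participant(s) in more than one training group: {list(multi.index)}"
        )
    if matrix is not None:
        mat = set(matrix.sample_ids)
        ann = set(annot["sample_id"])
        unannotated = mat - ann
        if unannotated:
            raise ValidationError(
                f"matrix sample(s) without annotation: {sorted(unannotated)}"
            )
        extra = ann - mat
        if extra:
            raise ValidationError(
                f"annotated sample(s) absent from matrix: {sorted(extra)}"
            )
    return annot


def validate_protein_annotation(
    annot: pd.DataFrame,
    matrix: QuantMatrix | None = None,
    vocabulary: Iterable[str] = FUNCTIONAL_GROUPS,
) -> pd.DataFrame:
    """Check protein-annotation invariants.

    ``functional_groups`` is a semicolon-separated label string (empty for
    none); labels must come from the declared vocabulary, and membership in
    a mitochondrial group requires the mitochondrial flag.
    """
    missing = set(PROTEIN_COLUMNS) - set(annot.columns)
    if missing:
        raise ValidationError(f"protein annotation missing column(s): {sorted(missing)}")
    annot = annot.copy()
    annot["protein_id"] = annot["protein_id"].astype(str)
    if annot["protein_id"].duplicated().any():
        dup = sorted(set(annot.loc[annot["protein_id"].duplicated(), "protein_id"]))
        raise ValidationError(f"duplicate protein id(s) in annotation: {dup}")
    annot["unique_peptides"] = annot["unique_peptides"].astype(int)
    for col in ("contaminant", "is_mitochondrial"):
        annot[col] = annot[col].map(_to_bool)
    bad = set(annot["confidence"]) - {"high", "other"}
    if bad:
        raise ValidationError(f"unknown confidence code(s): {sorted(bad)}")
    vocab = set(vocabulary)
    annot["functional_groups"] = annot["functional_groups"].fillna("").astype(str)
    for pid, label_str, is_mito in zip(
        annot["protein_id"], annot["functional_groups"], annot["is_mitochondrial"]
    ):
        labels = {s for s in label_str.split(";") if s}
        unknown = labels - vocab
        if unknown:
            raise ValidationError(
                f"protein {pid!r}: unknown functional group(s) {sorted(unknown)}"
            )
        if (labels & MITO_GROUPS) and not is_mito:
            raise ValidationError(
                f"protein {pid!r}: member of a mitochondrial group but not "
                "flagged mitochondrial"
            )
    if matrix is not None:
        unannotated = set(matrix.protein_ids) - set(annot["protein_id"])
        if unannotated:
            raise ValidationError(
                f"matrix protein(s) without annotation: {sorted(unannotated)[:5]}"
            )
    return annot


def read_annotations(
    sample_path: str | Path,
    protein_path: str | Path,
    matrix: QuantMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate sample and protein annotation TSVs."""
    samples = pd.read_csv(sample_path, sep="\t", dtype=str,
                          na_values=list(MISSING_TOKENS), keep_default_na=False)
    proteins = pd.read_csv(protein_path, sep="\t", dtype=str,
                           na_values=list(MISSING_TOKENS), keep_default_na=False)
    return (
        validate_sample_annotation(samples, matrix),
        validate_protein_annotation(proteins, matrix),
    )


def write_annotations(
    samples: pd.DataFrame, proteins: pd.DataFrame,
    sample_path: str | Path, protein_path: str | Path,
) -> None:
    samples.to_csv(sample_path, sep="\t", index=False, na_rep="NA")
    proteins.to_csv(protein_path, sep="\t", index=False, na_rep="NA")


def functional_group_members(annot: pd.DataFrame) -> dict[str, list[str]]:
    """Map each functional-group label to its member protein ids."""
    members: dict[str, list[str]] = {}
    for pid, label_str in zip(annot["protein_id"], annot["functional_groups"]):
        for label in str(label_str).split(";"):
            if label:
                members.setdefault(label, []).append(pid)
    return members


# ---------------------------------------------------------------------------
# Physiology fold-change reporting


def physiology_fold_change(pre_mean: float, post_mean: float) -> float:
    """Fold change of a physiological measure, post over pre group means."""
    if not pre_mean > 0:
        raise ValidationError(f"pre-training mean must be positive, got {pre_mean}")
    return post_mean / pre_mean


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def format_fold(fold: float) -> str:
    """Render a fold change as reported in text, e.g. ``'13-fold'``."""
    r = round_sig(fold, 2)
    if float(r).is_integer():
        return f"{int(r)}-fold"
    return f"{r:g}-fold"


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with study defaults."""

    max_missing_fraction: float = 0.30
    knn_k: int = 10
    trim_m: float = 0.30
    trim_a: float = 0.05
    de_alpha: float = 0.05
    lfc_display: float = 0.2
    n_permutations: int = 1000
    seed: int = 0
    log2_offset: float = 0.5
    combat_covariates: bool = True
    functional_group_vocabulary: list[str] = field(
        default_factory=lambda: list(FUNCTIONAL_GROUPS)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValidationError("max_missing_fraction must lie in [0, 1]")
        for name in ("trim_m", "trim_a"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ValidationError(f"{name} must lie in [0, 0.5)")
        if not 0.0 < self.de_alpha < 1.0:
            raise ValidationError("de_alpha must lie in (0, 1)")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ParseError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot interpret {x!r} as a boolean flag")


def write_report_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a derived report table with 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.6g")
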