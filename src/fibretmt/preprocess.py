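"""Identification filtering, missingness filtering and kNN imputation.

Clean-up rules: keep only proteins identified with high FDR confidence,
not flagged as contaminants, and with more than one unique peptide; then
drop proteins missing in strictly more than a fraction (default 30%) of
all samples, counted over the whole matrix rather than per group.
Remaining missing values are imputed by a protein-neighbour k-nearest-
neighbour average on the log2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LOG2, QuantMatrix, ValidationError


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step."""

    n_input: int
    n_removed_confidence: int
    n_removed_contaminant: int
    n_removed_unique_peptide: int
    n_removed_missing: int
    n_retained: int
    reasons: pd.Series  # protein_id -> reason code ("retained" if kept)

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_confidence + self.n_removed_contaminant
            + self.n_removed_unique_peptide + self.n_removed_missing
        )
        if self.n_input != removed + self.n_retained:
            raise ValidationError("filter report counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        return self.reasons.rename("reason").rename_axis("protein_id").reset_index()


def filter_by_confidence(
    matrix: QuantMatrix, protein_annot: pd.DataFrame
) -> tuple[QuantMatrix, FilterReport]:
    """Keep high-confidence, non-contaminant proteins with > 1 unique peptide.

    A protein failing several criteria is counted once, under the first
    failing criterion in the order confidence, contaminant, unique peptides.
    """
    annot = protein_annot.set_index("protein_id")
    unannotated = set(matrix.protein_ids) - set(annot.index)
    if unannotated:
        raise ValidationError(
            f"protein(s) without annotation: {sorted(unannotated)[:5]}"
        )
    annot = annot.loc[matrix.protein_ids]
    reasons = pd.Series("retained", index=matrix.data.index, dtype=object)
    not_high = annot["confidence"].astype(str) != "high"
    contaminant = annot["contaminant"].astype(bool)
    few_peptides = annot["unique_peptides"].astype(int) <= 1
    reasons[few_peptides.to_numpy()] = "unique_peptides<=1"
    reasons[contaminant.to_numpy()] = "contaminant"
    reasons[not_high.to_numpy()] = "low_confidence"
    keep = reasons == "retained"
    report = FilterReport(
        n_input=len(reasons),
        n_removed_confidence=int((reasons == "low_confidence").sum()),
        n_removed_contaminant=int((reasons == "contaminant").sum()),
        n_removed_unique_peptide=int((reasons == "unique_peptides<=1").sum()),
        n_removed_missing=0,
        n_retained=int(keep.sum()),
        reasons=reasons,
    )
    return matrix.with_data(matrix.data.loc[keep.to_numpy()]), report


def filter_missing(
    matrix: QuantMatrix, max_fraction: float = 0.30
) -> tuple[QuantMatrix, FilterReport]:
    """Drop proteins missing in strictly more than ``max_fraction`` of samples.

    The fraction is evaluated across the full matrix (all samples jointly);
    a protein missing in exactly 30% of samples is retained under the
    default threshold because the rule is "more than 30%".
    """
    if not 0.0 <= max_fraction <= 1.0:
        raise ValidationError("max_fraction must lie in [0, 1]")
    frac = matrix.data.isna().mean(axis=1)
    keep = frac <= max_fraction
    reasons = pd.Series(
        np.where(keep, "retained", "missing>threshold"), index=matrix.data.index
    )
    report = FilterReport(
        n_input=len(keep),
        n_removed_confidence=0,
        n_removed_contaminant=0,
        n_removed_unique_peptide=0,
        n_removed_missing=int((~keep).sum()),
        n_retained=int(keep.sum()),
        reasons=reasons,
    )
    return matrix.with_data(matrix.data.loc[keep]), report


def knn_impute(matrix: QuantMatrix, k: int = 10) -> QuantMatrix:
    """Impute missing log2 values from the k nearest proteins.

    Distance between two proteins is the root-mean-square difference over
    the samples observed in both (Euclidean distance rescaled by the number
    of shared observed samples), so proteins with different missingness
    patterns remain comparable. Each missing cell is filled with the
    unweighted mean, at that sample, of the k nearest proteins that are
    observed there. Ties in distance are broken by ascending protein id.

    Fallbacks: fewer than k eligible neighbours -> use all of them; no
    eligible neighbour at all -> the protein's own observed mean, with a
    warning. Observed entries are never altered.
    """
    if matrix.scale != LOG2:
        raise ValidationError("knn_impute expects a log2-scale matrix")
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = matrix.data.to_numpy().copy()
    ids = np.asarray(matrix.data.index)
    obs = ~np.isnan(X)
    target_rows = np.flatnonzero(~obs.all(axis=1))
    if target_rows.size == 0:
        return matrix.with_data(matrix.data.copy())

    X0 = np.where(obs, X, 0.0)
    obs_f = obs.astype(float)
    A0, Amask = X0[target_rows], obs_f[target_rows]
    # squared diffs restricted to shared observed samples, computed by masks
    shared = Amask @ obs_f.T
    sq = (A0 ** 2) @ obs_f.T + Amask @ (X0 ** 2).T - 2.0 * (A0 @ X0.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(sq, 0.0) / shared)
    dist[shared == 0] = np.nan

    out = X.copy()
    # stable tie-break: argsort over (distance, protein id rank)
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    for t, i in enumerate(target_rows):
        d = dist[t].copy()
        d[i] = np.nan  # a protein is not its own neighbour
        for j in np.flatnonzero(~obs[i]):
            eligible = np.flatnonzero(obs[:, j] & ~np.isnan(d))
            if eligible.size == 0:
                fallback = np.nanmean(X[i]) if obs[i].any() else np.nan
                warnings.warn(
                    f"no eligible kNN neighbour for protein {ids[i]!r} at "
                    f"sample column {j}; imputing the protein's observed mean",
                    stacklevel=2,
                )
                out[i, j] = fallback
                continue
            order = eligible[np.lexsort((id_rank[eligible], d[eligible]))]
            chosen = order[: min(k, order.size)]
            out[i, j] = X[chosen, j].mean()
    return matrix.with_data(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    )
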