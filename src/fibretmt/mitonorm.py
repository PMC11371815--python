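"""Mitochondrial protein enrichment and mitochondria-corrected abundances.

Type I fibres carry more mitochondria per unit muscle than type II fibres,
so a naive fibre-type comparison flags most mitochondrial proteins as
differential even when the composition of the mitochondrial proteome is
identical — the effect is a single global content multiplier, not
protein-specific remodelling. Two quantities address this:

* **MPE** (mitochondrial protein enrichment): per sample, the fraction of
  total detectable reporter intensity contributed by mitochondrial
  proteins; a proteomic proxy for mitochondrial content.
* **Mitochondria-corrected relative abundance**: the mitochondrial
  proteins are subset from the raw data and the full normalisation chain
  (SL -> TMM -> log2 -> ComBat) is re-run on the subset alone, equalising
  each sample's total mitochondrial signal so only composition differences
  remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import QuantMatrix, ValidationError
from .normalise import BatchModel, NormalisationFactors, normalise_chain


def mitochondrial_ids(protein_annot: pd.DataFrame) -> list[str]:
    """Protein ids flagged mitochondrial (MitoCarta/IMPI-style union list)."""
    flag = protein_annot["is_mitochondrial"].astype(bool)
    return list(protein_annot.loc[flag.to_numpy(), "protein_id"])


def read_mito_list(path) -> set[str]:
    """Read a mitochondrial gene list: one symbol per line, or a
    two-column TSV (symbol, evidence); lines starting with '#' are ignored."""
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.add(line.split("\t")[0])
    return symbols


# ---------------------------------------------------------------------------
# MPE


def compute_mpe(matrix: QuantMatrix, protein_annot: pd.DataFrame) -> pd.Series:
    """Per-sample mitochondrial protein enrichment.

    MPE(s) = (sum of raw-scale intensities of mitochondrial proteins in s)
    / (sum over all quantified proteins in s); missing entries are ignored
    in both sums. The ratio is invariant to any global per-sample scaling,
    so raw and SL-normalised inputs give the same value.
    """
    if (matrix.data < 0).any().any():
        raise ValidationError("MPE requires non-negative intensities")
    mito = set(mitochondrial_ids(protein_annot))
    is_mito = matrix.data.index.isin(mito)
    total = matrix.data.sum(axis=0, skipna=True)
    if (total <= 0).any():
        bad = list(total.index[total <= 0])
        raise ValidationError(f"sample(s) with zero total intensity: {bad}")
    mito_total = matrix.data.loc[is_mito].sum(axis=0, skipna=True)
    return (mito_total / total).rename("MPE")


def mpe_summary(mpe: pd.Series, sample_annot: pd.DataFrame) -> pd.DataFrame:
    """Group MPE by (fibre type, timepoint, training): mean, sd, n."""
    annot = sample_annot.set_index("sample_id")
    df = annot.join(mpe)
    return (
        df.groupby(["fibre_type", "timepoint", "training"])["MPE"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Mean mitochondrial protein expression


def mean_mito_expression(
    matrix: QuantMatrix,
    protein_annot: pd.DataFrame,
    sample_annot: pd.DataFrame,
    timepoint: str = "PRE",
) -> tuple[pd.DataFrame, dict]:
    """Per-sample mean mitochondrial log2 abundance and a paired I-vs-II test.

    Each participant must contribute both fibre types at the chosen
    timepoint. Returns the per-sample means plus a two-tailed paired
    t-test of type I vs type II across participants; a degenerate test
    (all differences equal) is reported with ``p = nan`` rather than
    raised.
    """
    mito = mitochondrial_ids(protein_annot)
    present = [p for p in mito if p in matrix.data.index]
    if not present:
        raise ValidationError("no mitochondrial proteins present in the matrix")
    means = matrix.data.loc[present].mean(axis=0).rename("mean_mito_log2")
    annot = sample_annot.set_index("sample_id")
    annot = annot[annot["timepoint"] == timepoint]
    table = annot.join(means, how="inner")

    pivot = table.pivot_table(
        index="participant_id", columns="fibre_type",
        values="mean_mito_log2", aggfunc="first",
    )
    for fibre in ("I", "II"):
        lacking = pivot.index[pivot.get(fibre, pd.Series(dtype=float)).isna()] \
            if fibre in pivot else pivot.index
        if len(lacking):
            raise ValidationError(
                f"participant(s) lacking a type {fibre} sample at {timepoint}: "
                f"{sorted(lacking)}"
            )
    d = pivot["I"] - pivot["II"]
    if np.allclose(d.std(ddof=1), 0.0):
        t_stat, p = (np.nan, np.nan) if np.allclose(d.mean(), 0.0) else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_rel(pivot["I"], pivot["II"])
    test = {
        "timepoint": timepoint,
        "n_pairs": int(len(pivot)),
        "mean_difference": float(d.mean()),
        "t": float(t_stat),
        "p": float(p),
    }
    return table.reset_index(), test


# ---------------------------------------------------------------------------
# Mitochondria-corrected renormalisation


def mito_renormalise(
    matrix: QuantMatrix,
    protein_annot: pd.DataFrame,
    sample_annot: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    zero_offset: float = 0.5,
    covariates: pd.DataFrame | None = None,
) -> tuple[QuantMatrix, NormalisationFactors, BatchModel]:
    """Re-normalise the mitochondrial subset from the raw scale.

    The mitochondrial proteins are subset from the complete raw matrix and
    the identical SL -> TMM -> log2 -> ComBat chain is applied to the
    subset alone. Equalising per-channel mitochondrial totals removes any
    global content multiplier by construction, so the corrected abundances
    compare mitochondrial *composition* between samples.
    """
    mito = [p for p in mitochondrial_ids(protein_annot) if p in matrix.data.index]
    if not mito:
        raise ValidationError("mitochondrial subset is empty")
    sub = matrix.subset_proteins(mito)
    zero = sub.data.sum(axis=0, skipna=True) <= 0
    if zero.any():
        raise ValidationError(
            "sample(s) with no mitochondrial signal: "
            f"{list(zero.index[zero])}"
        )
    return normalise_chain(
        sub, sample_annot, trim_m=trim_m, trim_a=trim_a,
        zero_offset=zero_offset, covariates=covariates,
    )


# ---------------------------------------------------------------------------
# Before/after comparison


@dataclass
class MitoNormComparison:
    """Status transitions of mitochondrial proteins across renormalisation."""

    n_before: int
    n_after: int
    n_overlap: int
    transitions: pd.DataFrame  # protein_id, sig_before, sig_after, status

    @property
    def n_before_only(self) -> int:
        return self.n_before - self.n_overlap

    @property
    def n_after_only(self) -> int:
        return self.n_after - self.n_overlap


def compare_before_after(
    before: pd.DataFrame, after: pd.DataFrame
) -> MitoNormComparison:
    """Compare DE significance before and after mitochondrial correction.

    Both tables must cover the identical protein universe and carry
    ``protein_id`` and ``significant`` columns (a DE table restricted to
    the mitochondrial subset).
    """
    b = before.set_index("protein_id")
    a = after.set_index("protein_id")
    if set(b.index) != set(a.index):
        raise ValidationError(
            "before/after tables cover different protein universes"
        )
    a = a.loc[b.index]
    sig_b = b["significant"].astype(bool)
    sig_a = a["significant"].astype(bool)
    status = np.select(
        [sig_b & sig_a, sig_b & ~sig_a, ~sig_b & sig_a],
        ["both", "before_only", "after_only"],
        default="neither",
    )
    transitions = pd.DataFrame({
        "protein_id": b.index,
        "sig_before": sig_b.to_numpy(),
        "sig_after": sig_a.to_numpy(),
        "status": status,
    })
    return MitoNormComparison(
        n_before=int(sig_b.sum()),
        n_after=int(sig_a.sum()),
        n_overlap=int((sig_b & sig_a).sum()),
        transitions=transitions,
    )
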