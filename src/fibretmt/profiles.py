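"""Functional-group profile analysis, clustering order and enrichment.

Profile analysis summarises a functional group (an OXPHOS complex, the
TCA cycle, beta-oxidation, the mitochondrial ribosome, ...) by the
per-sample mean of its members' z-scored abundances; the training
response is the change in that mean from PRE to POST (the "delta mean
z-score"), tested by a two-sided paired t-test across participants within
each (training group, fibre type) cell and BH-adjusted across the
displayed family.

Enrichment is a generic one-sided Fisher's exact test (hypergeometric
tail) of a hit set against a background over user-supplied term maps.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .diffexpr import bh_adjust
from .io import LOG2, QuantMatrix, ValidationError


# ---------------------------------------------------------------------------
# z-scoring


def zscore_scale(
    matrix: QuantMatrix, sample_ids: list[str] | None = None
) -> QuantMatrix:
    """Standardise each protein to mean 0, sd 1 over the declared samples.

    Zero-variance proteins cannot be standardised; they are dropped with a
    warning. The z-scores are computed within the declared sample set only
    (the comparison's own samples), which is also the set returned.
    """
    if matrix.scale != LOG2:
        raise ValidationError("z-scoring expects log2-scale data")
    sub = matrix if sample_ids is None else matrix.subset_samples(sample_ids)
    X = sub.data.to_numpy()
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance protein(s) from "
            "z-score scaling",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    out = pd.DataFrame(Z, index=sub.data.index, columns=sub.data.columns)
    return sub.with_data(out.loc[~flat])


# ---------------------------------------------------------------------------
# Delta mean z-score profiles


def group_delta_profile(
    zmatrix: QuantMatrix,
    groups: dict[str, list[str]],
    sample_annot: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """POST-minus-PRE change in per-sample group mean z, per design cell.

    For each functional group and each (training, fibre type) cell: the
    per-sample mean z over the group's members is averaged, the
    within-participant POST - PRE difference computed, and a two-sided
    paired t-test run across participants. P-values are BH-adjusted across
    the whole displayed family (all groups x cells). Cells with fewer than
    ``min_pairs`` pairs, or a degenerate (zero-variance) difference, report
    ``p = nan``.
    """
    annot = sample_annot.set_index("sample_id")
    annot = annot.loc[[s for s in zmatrix.sample_ids if s in annot.index]]
    rows = []
    for label, members in groups.items():
        present = [p for p in members if p in zmatrix.data.index]
        if not present:
            continue
        sample_mean = zmatrix.data.loc[present].mean(axis=0)
        for training in sorted(annot["training"].unique()):
            for fibre in sorted(annot["fibre_type"].unique()):
                cell = annot[
                    (annot["training"] == training)
                    & (annot["fibre_type"] == fibre)
                ]
                pivot = cell.reset_index().pivot_table(
                    index="participant_id", columns="timepoint",
                    values="sample_id", aggfunc="first",
                )
                if "PRE" not in pivot or "POST" not in pivot:
                    continue
                pivot = pivot.dropna()
                pre = sample_mean[pivot["PRE"]].to_numpy()
                post = sample_mean[pivot["POST"]].to_numpy()
                d = post - pre
                delta = float(d.mean()) if len(d) else np.nan
                if len(d) < min_pairs or np.allclose(d.std(ddof=1), 0.0):
                    t_stat, p = np.nan, np.nan
                else:
                    t_stat, p = stats.ttest_rel(post, pre)
                rows.append({
                    "group": label,
                    "training": training,
                    "fibre_type": fibre,
                    "n_members": len(present),
                    "n_pairs": len(d),
                    "delta_mean_z": delta,
                    "t": float(t_stat) if np.isfinite(t_stat) else t_stat,
                    "p": p,
                })
    profile = pd.DataFrame(rows)
    if len(profile):
        padj = np.full(len(profile), np.nan)
        ok = profile["p"].notna().to_numpy()
        if ok.any():
            padj[ok] = bh_adjust(profile.loc[ok, "p"].to_numpy())
        profile["p_adj"] = padj
    return profile


# ---------------------------------------------------------------------------
# Heatmap ordering


def cluster_heatmap_order(
    zmatrix: QuantMatrix,
) -> dict[str, object]:
    """Average-linkage (UPGMA) orderings of proteins and samples.

    Euclidean distances, agglomerative average linkage; the leaf order is
    the deterministic scipy dendrogram order (ties resolved by the lower
    original index merging first). Returns the row/column leaf orders and
    the two linkage matrices.
    """
    X = zmatrix.data.to_numpy()
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 rows and >= 2 columns")
    row_link = linkage(pdist(X), method="average")
    col_link = linkage(pdist(X.T), method="average")
    row_order = list(leaves_list(row_link))
    col_order = list(leaves_list(col_link))
    return {
        "row_order": [zmatrix.protein_ids[i] for i in row_order],
        "col_order": [zmatrix.sample_ids[i] for i in col_order],
        "row_linkage": row_link,
        "col_linkage": col_link,
    }


# ---------------------------------------------------------------------------
# Fisher enrichment


def fisher_enrichment(
    hits: set[str],
    background: set[str],
    term_map: dict[str, set[str]],
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation test per term.

    For each term the 2x2 table is (a) hits in the term, (b) hits outside
    it, (c) non-hit background in the term, (d) non-hit background outside
    it; the one-sided p is the hypergeometric upper tail P(X >= a), and
    p-values are BH-adjusted across terms. Terms are intersected with the
    background; hits must be a subset of the background.
    """
    hits = set(hits)
    background = set(background)
    stray = hits - background
    if stray:
        raise ValidationError(f"hit(s) not in background: {sorted(stray)[:5]}")
    if alternative != "greater":
        raise ValidationError("only the one-sided 'greater' alternative is supported")
    M = len(background)
    N = len(hits)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & background
        K = len(members)
        a = len(hits & members)
        b = N - a
        c = K - a
        d = M - K - b
        p = float(stats.hypergeom.sf(a - 1, M, K, N))
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append({
            "term": term, "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": odds, "p": p,
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


def read_term_map(path) -> dict[str, set[str]]:
    """Read a two-column TSV (term, gene symbol) into a term map."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, symbol = line.split("\t")[:2]
            mapping.setdefault(term, set()).add(symbol)
    return mapping
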