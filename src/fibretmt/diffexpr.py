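"""Differential expression: moderated t-statistics, BH adjustment,
fold-change/significance fusion scoring, and MDS sample coordinates.

The moderated t follows the standard empirical-Bayes variance-shrinkage
construction: per-protein residual variances s2_g with d_g degrees of
freedom are assumed to follow a scaled F distribution around a prior
(d0, s02) estimated from all proteins by moment matching on log s2; the
posterior variance (d0*s02 + d_g*s2_g)/(d0 + d_g) replaces s2_g in the
t-statistic, which gains d0 extra degrees of freedom.

The fusion score combines effect size and evidence for paired designs:
pi_g = |log2FC_g| * (-log10 p_g) with p_g from an ordinary paired t-test;
its null distribution is built by sign-flipping the within-pair
differences (exhaustively when the number of pairs allows, otherwise by
seeded sampling).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io import LOG2, QuantMatrix, ValidationError

P_FLOOR = np.nextafter(0.0, 1.0)  # smallest positive double, guards log10(0)


# ---------------------------------------------------------------------------
# Design helpers


def paired_design(
    sample_annot: pd.DataFrame, condition: pd.Series, treatment_level: str
) -> pd.DataFrame:
    """Design matrix with participant blocking plus a condition indicator.

    ``condition`` maps sample_id to a two-level factor; the returned design
    has one dummy per participant and a final ``__contrast__`` column that
    is 1 for ``treatment_level`` samples. The contrast coefficient is then
    the within-participant treatment-minus-baseline log2 difference.
    """
    annot = sample_annot.set_index("sample_id")
    participants = annot["participant_id"]
    design = pd.get_dummies(participants, dtype=float)
    design["__contrast__"] = (condition.loc[design.index] == treatment_level).astype(float)
    return design


def fibre_contrast_samples(
    sample_annot: pd.DataFrame, timepoint: str = "PRE", training: str | None = None
) -> pd.DataFrame:
    """Annotation subset for a type II vs type I contrast at one timepoint."""
    sel = sample_annot[sample_annot["timepoint"] == timepoint]
    if training is not None:
        sel = sel[sel["training"] == training]
    return sel.reset_index(drop=True)


def training_contrast_samples(
    sample_annot: pd.DataFrame, training: str, fibre_type: str
) -> pd.DataFrame:
    """Annotation subset for a POST vs PRE contrast in one (training, fibre) cell."""
    sel = sample_annot[
        (sample_annot["training"] == training)
        & (sample_annot["fibre_type"] == fibre_type)
    ]
    return sel.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Linear models and empirical-Bayes moderation


@dataclass
class ModeratedFit:
    """Per-protein linear-model fit, before and after variance moderation."""

    protein_ids: list[str]
    coef: np.ndarray              # (g,) contrast estimate, log2FC
    s2: np.ndarray                # (g,) residual variance
    df_residual: float            # d_g (shared across proteins)
    v: float                      # unscaled coefficient variance
    mean_abundance: np.ndarray    # (g,)
    zero_variance: np.ndarray = field(default=None)  # (g,) bool
    # set by eb_moderate:
    d0: float | None = None
    s02: float | None = None
    s2_post: np.ndarray | None = None
    t: np.ndarray | None = None
    p: np.ndarray | None = None


def fit_linear_models(
    matrix: QuantMatrix, design: pd.DataFrame, coef: str = "__contrast__"
) -> ModeratedFit:
    """Ordinary least squares per protein for one contrast coefficient.

    ``design`` is samples x parameters (numeric, full rank) covering every
    matrix sample; ``coef`` names the contrast column. Residual degrees of
    freedom must be positive.
    """
    if matrix.scale != LOG2:
        raise ValidationError("linear models expect log2-scale data")
    if matrix.data.isna().any().any():
        raise ValidationError("linear models require a complete matrix")
    missing = set(matrix.sample_ids) - set(design.index.astype(str))
    if missing:
        raise ValidationError(f"design misses sample(s): {sorted(missing)}")
    D = design.loc[matrix.sample_ids].to_numpy(float)
    n, p = D.shape
    if np.linalg.matrix_rank(D) < p:
        raise ValidationError("design matrix is rank deficient")
    if n - p <= 0:
        raise ValidationError(f"non-positive residual df ({n - p})")
    if coef not in design.columns:
        raise ValidationError(f"design has no column {coef!r}")
    c = list(design.columns).index(coef)

    X = matrix.data.to_numpy()
    xtx_inv = np.linalg.inv(D.T @ D)
    beta_all = X @ (xtx_inv @ D.T).T            # (g, p)
    resid = X - beta_all @ D.T
    df = n - p
    s2 = (resid ** 2).sum(axis=1) / df
    zero = s2 <= 1e-30
    return ModeratedFit(
        protein_ids=matrix.protein_ids,
        coef=beta_all[:, c],
        s2=s2,
        df_residual=float(df),
        v=float(xtx_inv[c, c]),
        mean_abundance=X.mean(axis=1),
        zero_variance=zero,
    )


def eb_moderate(
    fit: ModeratedFit, d0: float | None = None, s02: float | None = None
) -> ModeratedFit:
    """Shrink residual variances towards an empirical prior and re-test.

    When ``d0``/``s02`` are not given they are estimated by moment matching
    of log s2 against the theoretical log-F moments (digamma/trigamma);
    a degenerate variance distribution yields d0 = inf (complete shrinkage)
    with a warning flag rather than an error. Forcing ``d0=0`` reproduces
    the ordinary t-test; ``d0=inf`` gives s2_post = s02 everywhere.
    """
    ok = ~fit.zero_variance
    if d0 is None or s02 is None:
        if int(ok.sum()) < 20:
            raise ValidationError(
                "need >= 20 proteins with positive residual variance to "
                "estimate the variance prior"
            )
        est_d0, est_s02 = _fit_f_dist(fit.s2[ok], fit.df_residual)
        if d0 is None:
            d0 = est_d0
        if s02 is None:
            s02 = est_s02

    d = fit.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(fit.s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * fit.s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coef / np.sqrt(s2_post * fit.v)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    fit.d0, fit.s02, fit.s2_post, fit.t, fit.p = float(d0), float(s02), s2_post, t, p
    return fit


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of a scaled F prior to residual variances."""
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return float(d0), s02
    return float("inf"), float(np.exp(emean))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration on 1/x (monotone, stable)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


# ---------------------------------------------------------------------------
# Multiple testing and classification


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    fit: ModeratedFit, alpha: float = 0.05, lfc_display: float = 0.2,
    label_up: str = "up", label_down: str = "down",
) -> pd.DataFrame:
    """Moderated-fit results as a DEResult table with BH adjustment.

    Significance is decided by adjusted p alone (strict ``p_adj < alpha``);
    the log2FC bound only assigns display direction labels for significant
    proteins with |log2FC| beyond it.
    """
    if fit.p is None:
        raise ValidationError("run eb_moderate before building a DE table")
    p_adj = bh_adjust(fit.p)
    significant = p_adj < alpha
    direction = np.where(
        significant & (fit.coef > lfc_display), label_up,
        np.where(significant & (fit.coef < -lfc_display), label_down, ""),
    )
    return pd.DataFrame({
        "protein_id": fit.protein_ids,
        "log2FC": fit.coef,
        "mean_abundance": fit.mean_abundance,
        "t": fit.t,
        "p_raw": fit.p,
        "p_adj": p_adj,
        "significant": significant,
        "direction": direction,
    })


def classify_de(
    table: pd.DataFrame, alpha: float = 0.05, lfc_display: float = 0.2,
    label_up: str = "up", label_down: str = "down",
) -> pd.DataFrame:
    """(Re)label an existing DE table with the significance/direction rule."""
    out = table.copy()
    out["significant"] = out["p_adj"] < alpha
    out["direction"] = np.where(
        out["significant"] & (out["log2FC"] > lfc_display), label_up,
        np.where(out["significant"] & (out["log2FC"] < -lfc_display),
                 label_down, ""),
    )
    return out


# ---------------------------------------------------------------------------
# Fusion scheme


def paired_differences(
    matrix: QuantMatrix, sample_annot: pd.DataFrame,
    condition: pd.Series, treatment_level: str,
) -> pd.DataFrame:
    """Within-participant treatment-minus-baseline log2 differences.

    Returns proteins x participants; every participant must contribute
    exactly one sample at each level.
    """
    annot = sample_annot.set_index("sample_id")
    cond = condition.loc[annot.index]
    diffs = {}
    for pid, samples in annot.groupby("participant_id").groups.items():
        levels = cond.loc[list(samples)]
        treat = levels.index[levels == treatment_level]
        base = levels.index[levels != treatment_level]
        if len(treat) != 1 or len(base) != 1:
            raise ValidationError(
                f"participant {pid!r} is not a clean pair for this contrast"
            )
        diffs[pid] = matrix.data[treat[0]] - matrix.data[base[0]]
    return pd.DataFrame(diffs)


def fusion_scheme(
    diffs: pd.DataFrame, n_perm: int = 1000, seed: int = 0,
    exhaustive_max_pairs: int = 12,
) -> pd.DataFrame:
    """Fold-change x significance fusion scores with a sign-flip null.

    ``diffs`` holds proteins x pairs within-pair log2 differences. Per
    protein: paired-t p-value, log2FC (mean difference) and
    pi = |log2FC| * (-log10 p). The null distribution of pi comes from
    sign-flipping pairs — all 2^n patterns when n <= ``exhaustive_max_pairs``,
    else ``n_perm`` seeded draws — and the fusion significance is the
    fraction of null pi at least as large as the observed pi.
    """
    D = diffs.to_numpy(float)
    g, n = D.shape
    if n < 2:
        raise ValidationError("fusion scheme needs >= 2 pairs")
    lfc, p = _paired_t(D)
    pi = np.abs(lfc) * (-np.log10(np.maximum(p, P_FLOOR)))

    if n <= exhaustive_max_pairs:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        exhaustive = True
    else:
        if n_perm < 100:
            raise ValidationError("n_perm must be >= 100 for sampled nulls")
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        exhaustive = False

    count = np.zeros(g)
    for s in signs:
        lfc0, p0 = _paired_t(D * s[None, :])
        pi0 = np.abs(lfc0) * (-np.log10(np.maximum(p0, P_FLOOR)))
        count += pi0 >= pi
    fusion_p = count / signs.shape[0]
    return pd.DataFrame({
        "protein_id": diffs.index,
        "log2FC": lfc,
        "p_raw": p,
        "pi": pi,
        "fusion_p": fusion_p,
        "n_null": signs.shape[0],
        "exhaustive": exhaustive,
        "seed": seed,
    })


def _paired_t(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-sample t on within-pair differences."""
    n = D.shape[1]
    mean = D.mean(axis=1)
    sd = D.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(np.isnan(t), 1.0, p)   # zero mean & zero sd: no evidence
    return mean, p


# ---------------------------------------------------------------------------
# MDS


def mds_coordinates(matrix: QuantMatrix, top_n: int = 500) -> pd.DataFrame:
    """Classical 2-D MDS of samples on top-difference distances.

    The distance between two samples is the root-mean-square of their
    ``top_n`` largest absolute log2 differences (pairwise top set, the
    convention for expression MDS plots); the embedding is the classical
    Torgerson eigendecomposition of the double-centred squared distances.
    """
    if matrix.data.isna().any().any():
        raise ValidationError("MDS requires a complete matrix")
    X = matrix.data.to_numpy()
    g, n = X.shape
    if n < 3:
        raise ValidationError("MDS needs >= 3 samples")
    k = min(top_n, g)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sq = (X[:, i] - X[:, j]) ** 2
            top = np.partition(sq, g - k)[g - k:]
            D[i, j] = D[j, i] = np.sqrt(top.mean())
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:2]
    coords = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    for d in range(coords.shape[1]):   # deterministic sign convention
        i = int(np.argmax(np.abs(coords[:, d])))
        if coords[i, d] < 0:
            coords[:, d] = -coords[:, d]
    return pd.DataFrame(coords, index=matrix.sample_ids, columns=["dim1", "dim2"])
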