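"""Normalisation chain for multi-plex TMT reporter intensities.

Order of operations, fixed by convention for isobaric-label workflows:

1. **Sample loading (SL)** — within each TMT plex, scale every channel so
   all channels have the same total signal (equal loading assumption).
2. **TMM** — one multiplicative factor per sample from the trimmed mean of
   M-values against a reference sample, down-weighting extreme log-ratios
   and extreme-abundance proteins.
3. **log2 transform** — downstream linear models operate on log2 abundances.
4. **ComBat** — parametric empirical-Bayes location/scale batch adjustment
   across plexes, preserving declared biological covariates.

The ComBat implementation follows the standard parametric algorithm
(standardise per gene, per-batch location/scale estimates, normal /
inverse-gamma priors with method-of-moments hyperparameters, iterative
posterior solution) and is cross-checked in the test suite against the
Bioconductor ``sva::ComBat`` reference on frozen toy fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LOG2, RAW, QuantMatrix, ValidationError


@dataclass
class NormalisationFactors:
    """Per-sample scaling factors from SL and TMM."""

    sl: pd.Series | None = None      # sample_id -> SL factor (> 0)
    tmm: pd.Series | None = None     # sample_id -> TMM factor (> 0, product 1)
    reference: str | None = None     # TMM reference sample id
    trim_m: float = 0.30
    trim_a: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sl", "tmm"):
            s = getattr(self, name)
            if s is not None and not (s > 0).all():
                raise ValidationError(f"{name} factors must all be positive")


# ---------------------------------------------------------------------------
# Sample loading


def sample_loading_normalise(
    matrix: QuantMatrix, plex_map: pd.Series
) -> tuple[QuantMatrix, NormalisationFactors]:
    """Equalise total signal per channel within each plex.

    Each channel is scaled by (mean of the channel totals of its plex) /
    (its own total); totals ignore missing entries. After scaling, all
    column totals within a plex are equal.
    """
    if matrix.scale != RAW:
        raise ValidationError("sample loading expects a raw-scale matrix")
    plex_map = plex_map.astype(str)
    missing = set(matrix.sample_ids) - set(plex_map.index)
    if missing:
        raise ValidationError(f"sample(s) without plex assignment: {sorted(missing)}")
    totals = matrix.data.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"zero or negative channel total for sample(s): {bad}")
    factors = pd.Series(index=totals.index, dtype=float)
    for _, samples in plex_map.loc[totals.index].groupby(plex_map):
        t = totals[samples.index]
        factors[samples.index] = t.mean() / t
    scaled = matrix.data * factors
    return (
        matrix.with_data(scaled),
        NormalisationFactors(sl=factors.rename("sl_factor")),
    )


# ---------------------------------------------------------------------------
# TMM


def tmm_factors(
    matrix: QuantMatrix,
    reference: str = "auto",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_retained: int = 10,
) -> NormalisationFactors:
    """Trimmed-mean-of-M-values scaling factors for each sample.

    For sample s against reference r, over proteins positive and observed
    in both, with relative abundances p = x / (column total):

    * ``M = log2(p_s / p_r)``, ``A = 0.5 * log2(p_s * p_r)``;
    * drop the top and bottom ``trim_m`` quantiles of M and ``trim_a`` of A;
    * the log2 factor is the precision-weighted mean of the retained M,
      with inverse asymptotic (delta-method binomial) variances as weights.

    Factors are rescaled to have product 1. ``reference="auto"`` picks the
    sample whose upper-quartile relative abundance is closest to the mean
    of upper quartiles.
    """
    if matrix.scale != RAW:
        raise ValidationError("TMM expects a raw-scale matrix")
    X = matrix.data.to_numpy()
    samples = matrix.sample_ids
    totals = np.nansum(np.where(X > 0, X, np.nan), axis=0)
    P = X / totals[None, :]

    if reference == "auto":
        uq = np.array([
            np.nanquantile(np.where(col > 0, col, np.nan), 0.75) for col in P.T
        ])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if reference not in samples:
            raise ValidationError(f"unknown reference sample {reference!r}")
        ref_idx = samples.index(reference)

    log2f = np.zeros(len(samples))
    for j in range(len(samples)):
        if j == ref_idx:
            continue
        log2f[j] = _tmm_pair(
            X[:, j], X[:, ref_idx], totals[j], totals[ref_idx], trim_m, trim_a,
            min_retained,
        )
    factors = np.exp2(log2f)
    factors /= np.exp(np.mean(np.log(factors)))  # product exactly 1
    return NormalisationFactors(
        tmm=pd.Series(factors, index=samples, name="tmm_factor"),
        reference=samples[ref_idx],
        trim_m=trim_m,
        trim_a=trim_a,
    )


def _tmm_pair(
    xs: np.ndarray, xr: np.ndarray, ns: float, nr: float,
    trim_m: float, trim_a: float, min_retained: int = 10,
) -> float:
    """Weighted trimmed mean of M for one sample/reference pair (log2)."""
    ok = np.isfinite(xs) & np.isfinite(xr) & (xs > 0) & (xr > 0)
    xs, xr = xs[ok], xr[ok]
    M = np.log2((xs / ns) / (xr / nr))
    A = 0.5 * np.log2((xs / ns) * (xr / nr))
    w = (ns - xs) / (ns * xs) + (nr - xr) / (nr * xr)
    finite = np.isfinite(M) & np.isfinite(A) & (w > 0)
    M, A, w = M[finite], A[finite], w[finite]
    n = M.size
    # rank-based two-sided trimming on M and A jointly
    rank_m = _rank(M)
    rank_a = _rank(A)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < min_retained:
        raise ValidationError(
            f"only {int(keep.sum())} proteins retained after TMM trimming; "
            "reduce trim_m/trim_a"
        )
    wt = 1.0 / w[keep]
    return float(np.sum(wt * M[keep]) / np.sum(wt))


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based (matching R's rank())."""
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def apply_tmm(matrix: QuantMatrix, factors: NormalisationFactors) -> QuantMatrix:
    """Divide each sample by its TMM factor."""
    if factors.tmm is None:
        raise ValidationError("factors carry no TMM component")
    return matrix.with_data(matrix.data / factors.tmm)


# ---------------------------------------------------------------------------
# log2


def log2_transform(matrix: QuantMatrix, zero_offset: float = 0.5) -> QuantMatrix:
    """Elementwise log2; ``zero_offset`` is added to exact zeros only."""
    if matrix.scale != RAW:
        raise ValidationError("log2_transform expects a raw-scale matrix")
    vals = matrix.data.to_numpy().copy()
    if np.any(vals < 0):
        raise ValidationError("log2_transform requires non-negative entries")
    vals[vals == 0] = zero_offset
    return matrix.with_data(
        pd.DataFrame(np.log2(vals), index=matrix.data.index,
                     columns=matrix.data.columns),
        scale=LOG2,
    )


# ---------------------------------------------------------------------------
# ComBat


@dataclass
class BatchModel:
    """Fitted parameters of the empirical-Bayes batch adjustment."""

    batches: list[str]
    grand_mean: np.ndarray        # (g,)
    var_pooled: np.ndarray        # (g,)
    gamma_hat: np.ndarray         # (B, g) per-batch location estimates
    delta_hat: np.ndarray         # (B, g) per-batch scale estimates
    gamma_bar: np.ndarray         # (B,) prior means
    tau2: np.ndarray              # (B,) prior variances
    a_prior: np.ndarray           # (B,) inverse-gamma shape
    b_prior: np.ndarray           # (B,) inverse-gamma scale
    gamma_star: np.ndarray        # (B, g) EB-shrunk locations
    delta_star: np.ndarray        # (B, g) EB-shrunk scales

    def __post_init__(self) -> None:
        if np.any(self.delta_star <= 0):
            raise ValidationError("shrunk batch scale estimates must be > 0")


def combat_correct(
    matrix: QuantMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    conv_tol: float = 1e-4,
) -> tuple[QuantMatrix, BatchModel]:
    """Parametric empirical-Bayes batch correction on log2 data.

    Per gene the data are standardised by the fitted grand mean (plus any
    biological covariate effects) and the pooled variance; per-batch
    location and scale estimates are shrunk towards common parametric
    priors (normal for location, inverse-gamma for scale, hyperparameters
    by method of moments, joint posterior solved iteratively); the
    adjusted data replace batch effects by their shrunk estimates and
    restore the fitted mean. Biological covariates supplied in ``covariates``
    (numeric design columns indexed by sample, no intercept) are preserved.

    A single batch is returned unchanged. Confounding between batch and
    covariates is rejected by a rank check.
    """
    if matrix.scale != LOG2:
        raise ValidationError("combat expects a log2-scale matrix")
    if matrix.data.isna().any().any():
        raise ValidationError("combat requires a complete matrix (impute first)")
    samples = matrix.sample_ids
    batch = batch.astype(str).loc[samples]
    batches = list(dict.fromkeys(batch))
    X = matrix.data.to_numpy()
    g, n = X.shape

    if len(batches) == 1:
        model = _trivial_batch_model(batches, X)
        return matrix.with_data(matrix.data.copy()), model

    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(
            f"batch(es) with fewer than 2 samples: {list(small.index)}"
        )

    Z_batch = np.column_stack([(batch == b).to_numpy(float) for b in batches])
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[samples].to_numpy(float)
        design = np.hstack([Z_batch, cov])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError(
                "batch is confounded with the biological covariates "
                "(combined design is rank deficient)"
            )
    else:
        cov = None
        design = Z_batch

    n_batches = Z_batch.sum(axis=0)
    B_hat, *_ = np.linalg.lstsq(design, X.T, rcond=None)   # (p, g)
    grand_mean = (n_batches / n) @ B_hat[: len(batches)]
    fitted = design @ B_hat                                 # (n, g)
    var_pooled = np.mean((X.T - fitted) ** 2, axis=0)       # divisor n
    if np.any(var_pooled <= 0):
        raise ValidationError("gene(s) with zero pooled variance; cannot standardise")
    stand_mean = np.tile(grand_mean[:, None], (1, n))
    if cov is not None:
        stand_mean = stand_mean + (cov @ B_hat[len(batches):]).T
    sd = np.sqrt(var_pooled)[:, None]
    Z = (X - stand_mean) / sd

    gamma_hat = np.empty((len(batches), g))
    delta_hat = np.empty((len(batches), g))
    for i, b in enumerate(batches):
        idx = (batch == b).to_numpy()
        Zb = Z[:, idx]
        gamma_hat[i] = Zb.mean(axis=1)
        delta_hat[i] = Zb.var(axis=1, ddof=1)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2.0 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, b in enumerate(batches):
        idx = (batch == b).to_numpy()
        if s2[i] <= 0 or not np.isfinite(a_prior[i]):
            # degenerate scale distribution: no information to shrink with
            gamma_star[i] = (
                gamma_hat[i] if tau2[i] <= 0 else
                _shrink_location(gamma_hat[i], delta_hat[i], gamma_bar[i],
                                 tau2[i], int(n_batches[i]))
            )
            delta_star[i] = delta_hat[i]
            continue
        gamma_star[i], delta_star[i] = _it_solve(
            Z[:, idx], gamma_hat[i], delta_hat[i], gamma_bar[i], tau2[i],
            a_prior[i], b_prior[i], conv_tol,
        )

    adjusted = Z.copy()
    for i, b in enumerate(batches):
        idx = (batch == b).to_numpy()
        adjusted[:, idx] = (
            (Z[:, idx] - gamma_star[i][:, None]) / np.sqrt(delta_star[i])[:, None]
        )
    out = adjusted * sd + stand_mean
    model = BatchModel(
        batches=batches, grand_mean=grand_mean, var_pooled=var_pooled,
        gamma_hat=gamma_hat, delta_hat=delta_hat, gamma_bar=gamma_bar,
        tau2=tau2, a_prior=a_prior, b_prior=b_prior,
        gamma_star=gamma_star, delta_star=delta_star,
    )
    return matrix.with_data(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    ), model


def _shrink_location(
    gamma_hat: np.ndarray, delta: np.ndarray, gamma_bar: float, tau2: float, nb: int
) -> np.ndarray:
    return (nb * tau2 * gamma_hat + delta * gamma_bar) / (nb * tau2 + delta)


def _it_solve(
    Zb: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
    g_bar: float, t2: float, a: float, b: float, conv: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative joint posterior for one batch's location/scale parameters."""
    nb = Zb.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _shrink_location(g_hat, d_old, g_bar, t2, nb)
        sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (b + 0.5 * sum2) / (nb / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def _trivial_batch_model(batches: list[str], X: np.ndarray) -> BatchModel:
    g = X.shape[0]
    zeros, ones = np.zeros((1, g)), np.ones((1, g))
    return BatchModel(
        batches=batches, grand_mean=X.mean(axis=1),
        var_pooled=np.maximum(X.var(axis=1), 1e-30),
        gamma_hat=zeros.copy(), delta_hat=ones.copy(),
        gamma_bar=np.zeros(1), tau2=np.zeros(1),
        a_prior=np.zeros(1), b_prior=np.zeros(1),
        gamma_star=zeros.copy(), delta_star=ones.copy(),
    )


# ---------------------------------------------------------------------------
# Full chain


def normalise_chain(
    matrix: QuantMatrix,
    sample_annot: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    zero_offset: float = 0.5,
    covariates: pd.DataFrame | None = None,
) -> tuple[QuantMatrix, NormalisationFactors, BatchModel]:
    """SL -> TMM -> log2 -> ComBat on a complete raw-scale matrix."""
    plex_map = sample_annot.set_index("sample_id")["plex_id"]
    sl_matrix, factors = sample_loading_normalise(matrix, plex_map)
    tmm = tmm_factors(sl_matrix, trim_m=trim_m, trim_a=trim_a)
    factors.tmm, factors.reference = tmm.tmm, tmm.reference
    factors.trim_m, factors.trim_a = trim_m, trim_a
    scaled = apply_tmm(sl_matrix, tmm)
    logged = log2_transform(scaled, zero_offset=zero_offset)
    corrected, model = combat_correct(logged, plex_map, covariates=covariates)
    return corrected, factors, model
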