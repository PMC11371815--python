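"""Synthetic single-fibre TMT cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes for pooled-single-fibre TMT data:

* a 2-group (MICT/SIT) x 2-fibre-type (I/II) x 2-timepoint (PRE/POST)
  within-participant design, packed into 16-channel TMT plexes;
* log2-additive protein effects (lognormal reporter intensities):
  per-protein baseline, fibre-type effects on designated contractile and
  mitochondrial markers, per-(training, fibre) training responses;
* a *global mitochondrial-content multiplier* per (fibre, timepoint,
  training) cell applied to every mitochondrial protein of a sample —
  the content confound that mitochondrial renormalisation targets;
* plex-level location/scale batch effects, per-channel loading factors,
  and intensity-dependent (logistic on log2 intensity) plus uniform
  random missingness.

Fibre pools, not individual fibres, are the sampling unit. Every random
draw comes from one explicitly seeded generator; identical (params, seed)
give a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (
    FIBRE_TYPES,
    RAW,
    TIMEPOINTS,
    TRAINING_GROUPS,
    QuantMatrix,
    ValidationError,
    validate_protein_annotation,
    validate_sample_annotation,
)

#: TMTpro 16-plex reporter channel labels.
TMT16_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
)

Cell = tuple[str, str, str]  # (fibre_type, timepoint, training)


def _default_mito_multiplier() -> dict[Cell, float]:
    """Mitochondrial-content multipliers per (fibre, timepoint, training).

    The default encodes a higher mitochondrial content in type I fibres
    (content ratio 1.5) with no training-induced content change; training
    responses are added by overriding POST cells.
    """
    mult = {}
    for fibre in FIBRE_TYPES:
        for tp in TIMEPOINTS:
            for tr in TRAINING_GROUPS:
                mult[(fibre, tp, tr)] = 1.5 if fibre == "I" else 1.0
    return mult


@dataclass
class CohortParams:
    """Generator settings for one synthetic cohort.

    Effect sizes are on the log2 scale. The defaults describe a cohort of
    16 participants (8 per training group), 64 fibre-pool samples in four
    16-channel plexes and 2000 proteins of which 25% are mitochondrial —
    the design geometry of the study the pipeline targets.
    """

    n_participants_per_group: int = 8
    n_proteins: int = 2000
    frac_mitochondrial: float = 0.25
    plex_size: int = 16
    allow_partial_plex: bool = False

    # baseline abundance and residual noise
    baseline_mean: float = 16.0        # mean log2 reporter intensity
    baseline_sd: float = 2.0
    sigma0: float = 0.30               # prior residual sd scale
    sigma_df: float = 4.0              # residual variances ~ sigma0^2 * df / chi2(df)

    # per-protein biology
    frac_fibre_de: float = 0.15        # proteins with a fibre-type effect
    fibre_effect_sd: float = 0.6
    frac_train_de: float = 0.05        # proteins with a training response per cell
    train_effect_sd: float = 0.4

    # global mitochondrial content multiplier per design cell (linear scale)
    mito_multiplier: dict[Cell, float] = field(default_factory=_default_mito_multiplier)

    # technical structure
    batch_location_sd: float = 0.30    # gamma_bg ~ N(0, sd)
    batch_scale_log_sd: float = 0.10   # delta_bg = exp(N(0, sd))
    loading_log2_sd: float = 0.20      # channel loading 2^N(0, sd)

    # missingness: P(missing | x) = expit(a + b x) + random rate
    missing_intercept: float = 5.0
    missing_slope: float = -0.5
    missing_random_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.n_participants_per_group < 2:
            raise ValidationError("need >= 2 participants per training group")
        if self.n_proteins < 50:
            raise ValidationError("need >= 50 proteins")
        if not 0.0 < self.frac_mitochondrial < 1.0:
            raise ValidationError("frac_mitochondrial must lie in (0, 1)")
        for cell, m in self.mito_multiplier.items():
            if not m > 0:
                raise ValidationError(f"mito multiplier for {cell} must be > 0")


def null_params(**overrides) -> CohortParams:
    """A pure-null parameterisation: no biology, no batch/loading/missingness.

    Convenient for false-discovery-rate calibration experiments.
    """
    base = dict(
        frac_fibre_de=0.0,
        fibre_effect_sd=0.0,
        frac_train_de=0.0,
        train_effect_sd=0.0,
        mito_multiplier={
            (f, t, g): 1.0
            for f in FIBRE_TYPES for t in TIMEPOINTS for g in TRAINING_GROUPS
        },
        batch_location_sd=0.0,
        batch_scale_log_sd=0.0,
        loading_log2_sd=0.0,
        missing_intercept=-50.0,
        missing_slope=0.0,
        missing_random_rate=0.0,
    )
    base.update(overrides)
    return CohortParams(**base)


@dataclass
class SyntheticTruth:
    """Ground-truth parameters realised for one generated cohort."""

    seed: int
    params: CohortParams
    protein_ids: list[str]
    sample_ids: list[str]
    mu: np.ndarray                       # (g,) baseline log2 abundance
    beta_fibre: np.ndarray               # (g,) added to type II samples
    beta_train: dict[tuple[str, str], np.ndarray]  # (training, fibre) -> (g,)
    is_mitochondrial: np.ndarray         # (g,) bool
    batch_location: np.ndarray           # (n_plex, g)
    batch_scale: np.ndarray              # (n_plex, g), > 0
    channel_loading: np.ndarray          # (s,), > 0
    sigma: np.ndarray                    # (g,), > 0

    def __post_init__(self) -> None:
        if not (self.batch_scale > 0).all():
            raise ValidationError("batch scale factors must be > 0")
        if not (self.channel_loading > 0).all():
            raise ValidationError("channel loading factors must be > 0")
        if not (self.sigma > 0).all():
            raise ValidationError("residual sds must be > 0")

    def fibre_de_labels(self) -> np.ndarray:
        """True per-protein fibre-type differential-expression labels."""
        return self.beta_fibre != 0.0

    def to_frame(self) -> pd.DataFrame:
        """Per-protein truth as a table (for the truth TSV export)."""
        df = pd.DataFrame({
            "protein_id": self.protein_ids,
            "mu": self.mu,
            "beta_fibre": self.beta_fibre,
            "is_mitochondrial": self.is_mitochondrial,
            "sigma": self.sigma,
        })
        for (tr, fb), beta in sorted(self.beta_train.items()):
            df[f"beta_train_{tr}_{fb}"] = beta
        return df


def design_table(params: CohortParams) -> pd.DataFrame:
    """The sample annotation implied by the cohort design.

    Participants of both training groups are interleaved across plexes so
    every plex contains a mixture of conditions (four participants with all
    four of their fibre x timepoint pools per 16-channel plex).
    """
    n = params.n_participants_per_group
    participants = [(f"P{i + 1:02d}", "MICT") for i in range(n)] + [
        (f"P{i + n + 1:02d}", "SIT") for i in range(n)
    ]
    # interleave MICT/SIT so plex blocks mix training groups
    order: list[tuple[str, str]] = []
    for i in range(n):
        order.append(participants[i])
        order.append(participants[i + n])
    rows = []
    for pid, training in order:
        for fibre in FIBRE_TYPES:
            for tp in TIMEPOINTS:
                rows.append({
                    "sample_id": f"{pid}_{fibre}_{tp}",
                    "participant_id": pid,
                    "fibre_type": fibre,
                    "timepoint": tp,
                    "training": training,
                })
    annot = pd.DataFrame(rows)
    n_samples = len(annot)
    if n_samples % params.plex_size and not params.allow_partial_plex:
        raise ValidationError(
            f"{n_samples} samples do not pack into {params.plex_size}-channel "
            "plexes; set allow_partial_plex to permit a partial plex"
        )
    plex_idx = np.arange(n_samples) // params.plex_size
    annot["plex_id"] = [f"plex{i + 1}" for i in plex_idx]
    annot["channel_label"] = [
        TMT16_CHANNELS[i % params.plex_size] for i in range(n_samples)
    ]
    return annot


def generate_cohort(
    params: CohortParams | None = None, seed: int = 0
) -> tuple[QuantMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one cohort: raw matrix, annotations and ground truth.

    The raw reporter intensity of protein g in sample s is

    ``2 ** (mu_g + beta_fibre_g * [fibre II] + beta_train * [POST]
    + log2(m_cell) * [mito] + gamma_bg + eps * delta_bg) * loading_s``

    with missingness applied afterwards by :func:`inject_missing`.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    annot = design_table(params)
    g, s = params.n_proteins, len(annot)
    protein_ids = [f"PROT{i + 1:04d}" for i in range(g)]

    n_mito = int(round(params.frac_mitochondrial * g))
    is_mito = np.zeros(g, bool)
    is_mito[rng.choice(g, n_mito, replace=False)] = True

    mu = rng.normal(params.baseline_mean, params.baseline_sd, g)
    sigma = np.sqrt(
        params.sigma0 ** 2 * params.sigma_df / rng.chisquare(params.sigma_df, g)
    )

    beta_fibre = np.zeros(g)
    de_mask = rng.random(g) < params.frac_fibre_de
    beta_fibre[de_mask] = rng.normal(0.0, params.fibre_effect_sd, de_mask.sum())

    beta_train: dict[tuple[str, str], np.ndarray] = {}
    for tr in TRAINING_GROUPS:
        for fb in FIBRE_TYPES:
            beta = np.zeros(g)
            mask = rng.random(g) < params.frac_train_de
            beta[mask] = rng.normal(0.0, params.train_effect_sd, mask.sum())
            beta_train[(tr, fb)] = beta

    plexes = list(dict.fromkeys(annot["plex_id"]))
    gamma = rng.normal(0.0, params.batch_location_sd, (len(plexes), g)) \
        if params.batch_location_sd > 0 else np.zeros((len(plexes), g))
    delta = np.exp(rng.normal(0.0, params.batch_scale_log_sd, (len(plexes), g))) \
        if params.batch_scale_log_sd > 0 else np.ones((len(plexes), g))
    loading = np.exp2(rng.normal(0.0, params.loading_log2_sd, s)) \
        if params.loading_log2_sd > 0 else np.ones(s)

    plex_of = {p: i for i, p in enumerate(plexes)}
    log2x = np.empty((g, s))
    eps = rng.standard_normal((g, s))
    for j, row in enumerate(annot.itertuples(index=False)):
        b = plex_of[row.plex_id]
        cell_mult = params.mito_multiplier[(row.fibre_type, row.timepoint, row.training)]
        x = mu.copy()
        if row.fibre_type == "II":
            x += beta_fibre
        if row.timepoint == "POST":
            x += beta_train[(row.training, row.fibre_type)]
        x += np.log2(cell_mult) * is_mito
        x += gamma[b] + eps[:, j] * sigma * delta[b]
        log2x[:, j] = x
    raw = np.exp2(log2x) * loading[None, :]

    matrix = QuantMatrix(
        pd.DataFrame(raw, index=protein_ids, columns=list(annot["sample_id"])), RAW
    )
    truth = SyntheticTruth(
        seed=seed, params=params, protein_ids=protein_ids,
        sample_ids=list(annot["sample_id"]), mu=mu, beta_fibre=beta_fibre,
        beta_train=beta_train, is_mitochondrial=is_mito,
        batch_location=gamma, batch_scale=delta, channel_loading=loading,
        sigma=sigma,
    )
    matrix = inject_missing(
        matrix,
        intercept=params.missing_intercept,
        slope=params.missing_slope,
        random_rate=params.missing_random_rate,
        seed=rng.integers(0, 2 ** 31 - 1),
    )
    protein_annot = _protein_annotation(protein_ids, is_mito, rng)
    sample_annot = validate_sample_annotation(annot, matrix)
    protein_annot = validate_protein_annotation(protein_annot, matrix)
    return matrix, sample_annot, protein_annot, truth


def inject_missing(
    matrix: QuantMatrix,
    intercept: float,
    slope: float,
    random_rate: float,
    seed: int,
) -> QuantMatrix:
    """Apply intensity-dependent plus uniform random missingness.

    Each present raw entry x goes missing with probability
    ``expit(intercept + slope * log2(x))``, and independently with
    ``random_rate``. A negative slope makes low-abundance measurements
    likelier to drop out (left-censoring-like behaviour).
    """
    if matrix.scale != RAW:
        raise ValidationError("inject_missing expects a raw-scale matrix")
    if not 0.0 <= random_rate <= 1.0:
        raise ValidationError("random_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    vals = matrix.data.to_numpy().copy()
    with np.errstate(divide="ignore"):
        log2x = np.log2(np.where(vals > 0, vals, np.nan))
    p = expit(intercept + slope * log2x)
    p = np.where(np.isnan(p), 0.0, p)
    drop = rng.random(vals.shape) < p
    drop |= rng.random(vals.shape) < random_rate
    vals[drop] = np.nan
    return matrix.with_data(
        pd.DataFrame(vals, index=matrix.data.index, columns=matrix.data.columns)
    )


def _protein_annotation(
    protein_ids: list[str], is_mito: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Build a protein annotation consistent with the simulated truth.

    All simulated proteins are high-confidence non-contaminants with >= 2
    unique peptides (the generator models the post-identification matrix);
    functional groups are assigned to a subset of mitochondrial proteins
    (OXPHOS complexes, TCA, beta-oxidation, ribosome, dynamics) and of
    non-mitochondrial proteins (glycolysis, striated contraction).
    """
    g = len(protein_ids)
    groups = np.array([""] * g, dtype=object)
    mito_labels = ["CI", "CII", "CIII", "CIV", "CV", "MitoRibosome", "TCA",
                   "FattyAcidOxidation", "MitoDynamics"]
    other_labels = ["Glycolysis", "StriatedContraction"]
    mito_idx = np.flatnonzero(is_mito)
    other_idx = np.flatnonzero(~is_mito)
    n_grouped_mito = min(len(mito_idx), max(9, len(mito_idx) // 3))
    chosen = rng.choice(mito_idx, n_grouped_mito, replace=False)
    for i, idx in enumerate(chosen):
        groups[idx] = mito_labels[i % len(mito_labels)]
    n_grouped_other = min(len(other_idx), max(2, len(other_idx) // 20))
    chosen = rng.choice(other_idx, n_grouped_other, replace=False)
    for i, idx in enumerate(chosen):
        groups[idx] = other_labels[i % len(other_labels)]
    return pd.DataFrame({
        "protein_id": protein_ids,
        "gene_symbol": [f"GENE{i + 1:04d}" for i in range(g)],
        "unique_peptides": 2 + rng.integers(0, 20, g),
        "confidence": "high",
        "contaminant": False,
        "is_mitochondrial": is_mito,
        "functional_groups": groups,
    })


def write_cohort(
    outdir: str | Path,
    matrix: QuantMatrix,
    sample_annot: pd.DataFrame,
    protein_annot: pd.DataFrame,
    truth: SyntheticTruth,
) -> None:
    """Write the cohort TSVs (matrix, annotations, per-protein truth)."""
    from .io import write_annotations, write_quant_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_quant_matrix(matrix, outdir / "quant_raw.tsv")
    write_annotations(
        sample_annot, protein_annot,
        outdir / "samples.tsv", outdir / "proteins.tsv",
    )
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def with_mito_content(params: CohortParams, type_i: float, type_ii: float = 1.0,
                      ) -> CohortParams:
    """Params with a fibre-type mitochondrial content ratio and nothing else changed."""
    mult = {
        (f, t, g): (type_i if f == "I" else type_ii)
        for f in FIBRE_TYPES for t in TIMEPOINTS for g in TRAINING_GROUPS
    }
    return replace(params, mito_multiplier=mult)
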