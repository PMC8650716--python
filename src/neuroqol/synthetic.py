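"""Synthetic cohorts with the full statistical structure of the analysis.

The generator emulates a small MS cohort observed in a three-stage fMRI
stress paradigm (baseline 1, stress, baseline 2) at baseline visit T0 and
re-assessed with the HAQUAMS questionnaire at a follow-up visit T1.  It
plants every piece of structure the downstream pipeline is built to detect:

* regional mean CBF for each stage follows a latent-network factor model,
  ``X_stage = grand_mean + amplitude * S_stage @ L.T + g 1' + E``, with
  orthonormal, region-mean-free loading columns ``L``, stage-specific latent
  scores ``S`` (i.i.d. normal with per-network scale, plus a stress-stage
  mean shift of the designated network), a participant-level global GM
  offset ``g`` per stage and i.i.d. Gaussian voxel-average noise ``E``;
* the HAQUAMS change T1 - T0 depends linearly on the designated network's
  differential activity (standardized), on covariates, and Gaussian noise
  (with an optional outlier-contamination knob for robustness studies);
* perceived-stress ratings (stages I, III, V, VII; nine-point scale) and
  pulse rates (stages II, IV, VI) rise under stress and fall after
  cessation, with pulse optionally available for only a subset of
  participants (missing completely at random, mirroring the 21-of-28
  availability of the motivating design);
* baseline-2 fMRI may be missing for a configurable number of participants
  (default one, i.e. 27 of 28 with all three stages).

Defaults follow the motivating study design: 28 participants (23 RRMS / 5
SPMS, 18 women), follow-up 363-1169 days, 100 atlas regions.  The cognitive
task-load covariate, whose real distribution is unknown, is standard normal.
Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import haquams
from .networks import RegionalActivityMatrix, STAGES

RATING_STAGES: tuple[str, ...] = ("I", "III", "V", "VII")
PULSE_STAGES: tuple[str, ...] = ("II", "IV", "VI")


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class StageEffects:
    """Mean psychophysiological levels per stage.

    Ratings are on the nine-point perceived-stress scale; pulse in beats per
    minute.  The defaults plant an increase under stress and a return toward
    baseline after cessation.
    """

    rating_means: dict = field(
        default_factory=lambda: {"I": 2.5, "III": 2.5, "V": 4.5, "VII": 2.5}
    )
    pulse_means: dict = field(
        default_factory=lambda: {"II": 70.0, "IV": 80.0, "VI": 70.0}
    )
    rating_noise_sd: float = 0.8
    pulse_noise_sd: float = 3.0
    rating_intercept_sd: float = 0.8
    pulse_intercept_sd: float = 6.0

    def validate(self) -> None:
        if set(self.rating_means) != set(RATING_STAGES):
            raise ConfigurationError(f"rating means must cover stages {RATING_STAGES}")
        if set(self.pulse_means) != set(PULSE_STAGES):
            raise ConfigurationError(f"pulse means must cover stages {PULSE_STAGES}")
        if any(v <= 0 for v in self.pulse_means.values()):
            raise ConfigurationError("pulse means must be positive")
        for v in (
            self.rating_noise_sd,
            self.pulse_noise_sd,
            self.rating_intercept_sd,
            self.pulse_intercept_sd,
        ):
            if v < 0:
                raise ConfigurationError("noise scales must be >= 0")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-design defaults."""

    n_participants: int = 28
    n_regions: int = 100
    n_latent_networks: int = 5
    loading_matrix_spec: str = "random_orthonormal"  # or "blocks"
    #: per-network latent score standard deviations (distinct scales make the
    #: rotation of the latent space identifiable); default geometric decay
    network_score_scales: tuple | None = None
    #: index (0-based) of the network carrying the planted effects
    designated_network: int = 2
    #: stress-stage mean shift of the designated network's latent score
    stress_score_shift: float = 2.0
    #: standardized slope of the HAQUAMS change on the designated network's
    #: stress-exposure / stress-cessation differential activity
    exposure_effect_size: float = 0.0
    cessation_effect_size: float = 0.8
    planted_scale: str = "total"  # "total" or one subscale name
    noise_sd_cbf: float = 1.0  # ml/100 g/min, per region
    noise_sd_outcome: float = 0.1  # HAQUAMS units, per subscale change
    global_offset_sd: float = 5.0  # participant global GM CBF offset
    cbf_grand_mean: float = 50.0
    network_amplitude: float = 10.0  # ml/100 g/min per unit latent score
    covariate_effects: dict = field(
        default_factory=lambda: {"followup_days": 2e-4, "ms_type": 0.3}
    )
    outlier_fraction: float = 0.0
    outlier_sd: float = 2.0
    followup_days_range: tuple = (363, 1169)
    n_missing_baseline2: int = 1
    n_pulse_participants: int | None = None  # default: 3/4 of cohort (21 of 28)
    stage_effects: StageEffects = field(default_factory=StageEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_regions", "n_latent_networks"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_regions < self.n_participants:
            raise ConfigurationError(
                "n_regions must be >= n_participants (the component count "
                "equals the number of participants only for wide matrices)"
            )
        if self.n_latent_networks > min(self.n_participants, self.n_regions):
            raise ConfigurationError("too many latent networks for the matrix size")
        if not 0 <= self.designated_network < self.n_latent_networks:
            raise ConfigurationError("designated_network out of range")
        for name in ("noise_sd_cbf", "noise_sd_outcome", "global_offset_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.followup_days_range
        if lo > hi or lo <= 0:
            raise ConfigurationError("invalid followup_days_range")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigurationError("outlier_fraction must be in [0, 1)")
        if not 0 <= self.n_missing_baseline2 < self.n_participants:
            raise ConfigurationError("n_missing_baseline2 out of range")
        if self.planted_scale not in ("total",) + haquams.SUBSCALES:
            raise ConfigurationError(f"unknown planted_scale {self.planted_scale!r}")
        if self.network_score_scales is None:
            self.network_score_scales = tuple(
                1.5 * 0.85**j for j in range(self.n_latent_networks)
            )
        if len(self.network_score_scales) != self.n_latent_networks:
            raise ConfigurationError("network_score_scales length mismatch")
        self.stage_effects.validate()

    @property
    def n_pulse(self) -> int:
        if self.n_pulse_participants is not None:
            if not 2 <= self.n_pulse_participants <= self.n_participants:
                raise ConfigurationError("n_pulse_participants out of range")
            return self.n_pulse_participants
        return max(2, int(round(0.75 * self.n_participants)))


@dataclass
class OutcomePanel:
    """HAQUAMS outcomes plus covariates in analysis-ready form.

    ``items``: long item-level table; ``scores``: wide per-(participant,
    timepoint) scale scores; ``table``: one row per participant with
    ``<scale>_T0``, ``<scale>_T1``, ``delta_<scale>`` and all covariates.
    """

    items: pd.DataFrame
    scores: pd.DataFrame
    table: pd.DataFrame


@dataclass
class CohortDataset:
    """One synthetic cohort: covariates, stage matrices, outcomes,
    psychophysiology and the record of planted truth."""

    cohort_table: pd.DataFrame
    stage_matrices: dict
    outcomes: OutcomePanel
    psychophys: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# Loading patterns
# ---------------------------------------------------------------------------

def make_loadings(spec: str, n_regions: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Region-weight patterns for the latent networks.

    Columns are orthonormal and have zero region-mean, so the planted
    network structure is invariant under the per-participant global-mean
    centering applied downstream.
    """
    if spec == "random_orthonormal":
        raw = rng.standard_normal((n_regions, k))
    elif spec == "blocks":
        # disjoint blocks leaving a remainder of unweighted regions, so the
        # demeaned block indicators stay linearly independent
        width = n_regions // (k + 1)
        if width < 1:
            raise ConfigurationError("too few regions for block loadings")
        raw = np.zeros((n_regions, k))
        for j in range(k):
            raw[j * width : (j + 1) * width, j] = 1.0
    else:
        raise ConfigurationError(f"unknown loading_matrix_spec {spec!r}")
    raw = raw - raw.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(raw)
    q *= np.sign(np.diag(r))[None, :]  # deterministic orientation
    return q


# ---------------------------------------------------------------------------
# Psychophysiology
# ---------------------------------------------------------------------------

def generate_psychophys(
    cohort_table: pd.DataFrame,
    stage_effects: StageEffects,
    seed: int | np.random.Generator,
    pulse_participants=None,
) -> pd.DataFrame:
    """Long table of perceived-stress ratings and pulse rates per stage.

    Ratings are produced for stages I, III, V, VII by rounding a latent
    continuous value to the nine-point scale (clipped to [1, 9]); pulse for
    stages II, IV, VI, clipped away from zero.  ``pulse_participants``
    restricts pulse rows to a subset (missing completely at random).
    """
    stage_effects.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = cohort_table.index.to_numpy()
    n = ids.size
    rows = []
    rating_intercept = rng.normal(0, stage_effects.rating_intercept_sd, n)
    pulse_intercept = rng.normal(0, stage_effects.pulse_intercept_sd, n)
    if pulse_participants is None:
        pulse_participants = ids
    pulse_set = set(pulse_participants)
    for stage in RATING_STAGES:
        latent = (
            stage_effects.rating_means[stage]
            + rating_intercept
            + rng.normal(0, stage_effects.rating_noise_sd, n)
        )
        values = np.clip(np.rint(latent), 1, 9)
        for pid, v in zip(ids, values):
            rows.append((pid, stage, "rating", float(v)))
    for stage in PULSE_STAGES:
        values = (
            stage_effects.pulse_means[stage]
            + pulse_intercept
            + rng.normal(0, stage_effects.pulse_noise_sd, n)
        )
        values = np.maximum(values, 1.0)
        for pid, v in zip(ids, values):
            if pid in pulse_set:
                rows.append((pid, stage, "pulse", float(v)))
    return pd.DataFrame(rows, columns=["participant_id", "stage", "parameter", "value"])


# ---------------------------------------------------------------------------
# HAQUAMS item construction
# ---------------------------------------------------------------------------

def _items_for_target_mean(target: float, k: int) -> np.ndarray:
    """k ordinal items in [1, 5] whose mean is as close as possible to
    ``target`` (quantized to the 1/k grid)."""
    total = int(np.clip(np.rint(target * k), k, 5 * k))
    base, rem = divmod(total, k)
    items = np.full(k, base, dtype=float)
    items[:rem] += 1
    return items


def _item_rows(pid, timepoint: str, subscale: str, items: np.ndarray) -> list:
    return [
        (pid, timepoint, subscale, i + 1, float(v)) for i, v in enumerate(items)
    ]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _cohort_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    ids = pd.Index([f"P{i + 1:03d}" for i in range(n)], name="participant_id")
    n_spms = min(n - 1, max(1, int(round(5 / 28 * n)))) if n >= 2 else 0
    ms_type = np.array(["RRMS"] * n, dtype=object)
    ms_type[rng.choice(n, size=n_spms, replace=False)] = "SPMS"
    lo, hi = config.followup_days_range
    return pd.DataFrame(
        {
            "sex": rng.binomial(1, 18 / 28, n),  # 1 = female
            "age": rng.integers(27, 62, n).astype(float),
            "education": rng.binomial(1, 18 / 28, n),  # >= high-school diploma
            "edss": np.round(rng.uniform(1.0, 6.0, n) * 2) / 2,
            "relapse_rate": np.round(rng.exponential(0.4, n), 2),
            "t2_lesion_load": np.round(rng.lognormal(1.5, 0.8, n), 2),  # ml
            "ms_type": ms_type,
            "disease_duration": np.exp(
                rng.uniform(np.log(271), np.log(12250), n)
            ).round(),  # days since first manifestation
            "gm_fraction": np.clip(rng.normal(0.45, 0.03, n), 0.3, 0.6),
            "task_load": rng.standard_normal(n),
            "followup_days": rng.integers(lo, hi + 1, n).astype(float),
        },
        index=ids,
    )


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate one fully structured synthetic cohort (deterministic given
    ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    n, r, k = config.n_participants, config.n_regions, config.n_latent_networks
    cohort = _cohort_covariates(config, rng)
    ids = cohort.index

    # --- latent networks and stage scores -------------------------------
    L = make_loadings(config.loading_matrix_spec, r, k, rng)
    scales = np.asarray(config.network_score_scales, dtype=float)
    scores = {}
    for stage in STAGES:
        s = rng.standard_normal((n, k)) * scales[None, :]
        if stage == "stress":
            s[:, config.designated_network] += config.stress_score_shift
        scores[stage] = s

    # --- stage matrices --------------------------------------------------
    region_names = [f"region_{i + 1:03d}" for i in range(r)]
    stage_matrices = {}
    for stage in STAGES:
        g = rng.normal(0, config.global_offset_sd, n)
        E = rng.normal(0, config.noise_sd_cbf, (n, r))
        X = (
            config.cbf_grand_mean
            + config.network_amplitude * scores[stage] @ L.T
            + g[:, None]
            + E
        )
        stage_matrices[stage] = RegionalActivityMatrix(
            data=pd.DataFrame(X, index=ids, columns=region_names), stage=stage
        )
    missing_b2 = []
    if config.n_missing_baseline2:
        missing_b2 = list(
            rng.choice(ids.to_numpy(), size=config.n_missing_baseline2, replace=False)
        )
        b2 = stage_matrices["baseline2"]
        stage_matrices["baseline2"] = RegionalActivityMatrix(
            data=b2.data.drop(index=missing_b2), stage="baseline2"
        )

    # --- planted outcome model ------------------------------------------
    d = config.designated_network
    exposure_truth = scores["stress"][:, d] - scores["baseline1"][:, d]
    cessation_truth = scores["baseline2"][:, d] - scores["stress"][:, d]
    # standardize by the *theoretical* moments (difference of two iid normal
    # scores; the stress mean shift adds +shift to exposure, -shift to
    # cessation) so the planted effect is a pure slope and does not move the
    # cohort's mean outcome change
    sd_diff = np.sqrt(2.0) * scales[d]
    shift = config.stress_score_shift
    signal = (
        config.exposure_effect_size * (exposure_truth - shift) / sd_diff
        + config.cessation_effect_size * (cessation_truth + shift) / sd_diff
    )
    cov_terms = np.zeros(n)
    eff = config.covariate_effects
    if "followup_days" in eff:
        # worsening accumulates with elapsed follow-up time
        cov_terms += eff["followup_days"] * cohort["followup_days"].to_numpy()
    if "ms_type" in eff:
        cov_terms += eff["ms_type"] * (cohort["ms_type"] == "SPMS").to_numpy(float)
    if "task_load" in eff:
        cov_terms += eff["task_load"] * cohort["task_load"].to_numpy()

    item_rows: list = []
    for pid_idx, pid in enumerate(ids):
        for subscale in haquams.SUBSCALES:
            k_items = haquams.ITEM_COUNTS[subscale]
            m0 = float(np.clip(rng.normal(2.5, 0.6), 1.2, 4.2))
            t0_items = np.clip(np.rint(rng.normal(m0, 0.5, k_items)), 1, 5)
            item_rows += _item_rows(pid, "T0", subscale, t0_items)
            delta = cov_terms[pid_idx] + rng.normal(0, config.noise_sd_outcome)
            if config.outlier_fraction and rng.random() < config.outlier_fraction:
                delta += rng.normal(0, config.outlier_sd)
            if config.planted_scale == "total" or subscale == config.planted_scale:
                delta += signal[pid_idx]
            t1_target = float(np.clip(t0_items.mean() + delta, 1.0, 5.0))
            item_rows += _item_rows(
                pid, "T1", subscale, _items_for_target_mean(t1_target, k_items)
            )
    items = pd.DataFrame(
        item_rows,
        columns=["participant_id", "timepoint", "subscale", "item_index", "value"],
    )
    scores_wide = haquams.score_items(items)
    wide = scores_wide.pivot(index="participant_id", columns="timepoint")
    table = pd.DataFrame(index=ids)
    for scale in haquams.SCALES:
        table[f"{scale}_T0"] = wide[(scale, "T0")]
        table[f"{scale}_T1"] = wide[(scale, "T1")]
        table[f"delta_{scale}"] = table[f"{scale}_T1"] - table[f"{scale}_T0"]
    table = table.join(cohort)
    outcomes = OutcomePanel(items=items, scores=scores_wide, table=table)

    # --- psychophysiology -------------------------------------------------
    pulse_ids = rng.choice(ids.to_numpy(), size=config.n_pulse, replace=False)
    psychophys = generate_psychophys(
        cohort,
        config.stage_effects,
        np.random.default_rng(rng.integers(0, 2**31)),
        pulse_participants=pulse_ids,
    )

    truth = {
        "loadings": L,
        "scores": scores,
        "designated_network": d,
        "exposure_truth": exposure_truth,
        "cessation_truth": cessation_truth,
        "signal": signal,
        "exposure_effect_size": config.exposure_effect_size,
        "cessation_effect_size": config.cessation_effect_size,
        "planted_scale": config.planted_scale,
        "missing_baseline2": missing_b2,
        "pulse_participants": sorted(map(str, pulse_ids)),
        "seed": config.seed,
    }
    return CohortDataset(
        cohort_table=cohort,
        stage_matrices=stage_matrices,
        outcomes=outcomes,
        psychophys=psychophys,
        truth=truth,
    )


def match_designated_network(truth: dict, loadings: pd.DataFrame) -> str:
    """Name of the fitted component best aligned (max |cosine|) with the
    planted designated network's loading vector."""
    planted = truth["loadings"][:, truth["designated_network"]]
    mat = loadings.to_numpy()
    cos = np.abs(planted @ mat) / (
        np.linalg.norm(planted) * np.linalg.norm(mat, axis=0)
    )
    return str(loadings.columns[int(np.argmax(cos))])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_cohort(dataset: CohortDataset, out_dir) -> None:
    """Write all tables as UTF-8 CSV plus a JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.cohort_table.to_csv(out / "cohort.csv")
    for stage, mat in dataset.stage_matrices.items():
        mat.data.to_csv(out / f"cbf_{stage}.csv")
    dataset.outcomes.items.to_csv(out / "haquams_items.csv", index=False)
    dataset.outcomes.scores.to_csv(out / "haquams_scores.csv", index=False)
    dataset.outcomes.table.to_csv(out / "outcomes.csv")
    dataset.psychophys.to_csv(out / "psychophys.csv", index=False)
    (out / "truth.json").write_text(json.dumps(_jsonable(dataset.truth), indent=2))
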