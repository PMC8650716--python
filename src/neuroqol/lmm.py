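"""Linear mixed models with permutation inference for repeated measures.

Two families of analyses share one design: each participant contributes
exactly two occasions (an earlier and a later one), the fixed effect of
interest codes the occasion (0/1 stage code for psychophysiological stress
contrasts; 0 vs. follow-up days for longitudinal HRQoL change), fixed
nuisance covariates are participant-level (sex, age, MS type, task load), and
a per-participant random intercept absorbs between-participant level
differences.

Inference does not rely on the asymptotic t distribution: the null
distribution of the t statistic is built by independently flipping the
earlier/later occasion labels within each participant (2^n possible
relabelings, enumerated exhaustively or sampled), refitting the model for
every relabeling.  Under the null of no occasion effect the paired responses
are exchangeable within participant, so the flip group is a valid permutation
group.  One-sided p-values (with the add-one estimator for sampled flips)
implement the directional claims: an *increase* under stress exposure, a
*decrease* after stress cessation, a *worsening* (positive slope) for
longitudinal HRQoL.

Model fitting: the public :func:`fit_lmm` uses statsmodels ``MixedLM`` with
full maximum likelihood (ML rather than REML so likelihoods are comparable
across permutations).  Permutation loops use a profile-ML fitter specialized
to the balanced two-occasion random-intercept model: the 2n observations are
rotated into n within-pair differences (residual variance sigma^2) and n
pair means (variance sigma^2 + 2 tau^2), two independent Gaussian blocks
whose ML solution is a small coordinate-ascent iteration.  The specialized
fitter is cross-checked against ``MixedLM`` in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIRECTIONS = ("increase", "decrease", "two_sided")

#: The four psychophysiological stage contrasts: (parameter, earlier stage,
#: later stage, expected direction).
STAGE_CONTRASTS: tuple[tuple[str, str, str, str], ...] = (
    ("rating", "III", "V", "increase"),  # perceived stress under exposure
    ("pulse", "II", "IV", "increase"),  # pulse under exposure
    ("rating", "V", "VII", "decrease"),  # perceived stress after cessation
    ("pulse", "IV", "VI", "decrease"),  # pulse after cessation
)

_EXHAUSTIVE_LIMIT = 20  # 2^20 sign patterns is the enumeration ceiling


@dataclass
class RepeatedMeasuresDesign:
    """Balanced two-occasion repeated-measures design.

    ``y_earlier``/``y_later`` are the responses, ``x_earlier``/``x_later``
    the interest-regressor values, at the two occasions; ``covariates`` are
    participant-level nuisance columns (an intercept is appended).
    """

    y_earlier: np.ndarray
    y_later: np.ndarray
    x_earlier: np.ndarray
    x_later: np.ndarray
    covariates: pd.DataFrame | np.ndarray | None = None
    participant_ids: np.ndarray | None = None

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        y0 = np.asarray(self.y_earlier, dtype=float)
        y1 = np.asarray(self.y_later, dtype=float)
        x0 = np.asarray(self.x_earlier, dtype=float)
        x1 = np.asarray(self.x_later, dtype=float)
        if self.covariates is None:
            Z = np.empty((y0.size, 0))
        else:
            Z = np.asarray(self.covariates, dtype=float)
            if Z.ndim == 1:
                Z = Z[:, None]
        n = y0.size
        if not (y1.size == x0.size == x1.size == n and Z.shape[0] == n):
            raise ValueError("inconsistent design lengths")
        if n < 2:
            raise ValueError("need at least two participants")
        keep = (
            np.isfinite(y0)
            & np.isfinite(y1)
            & np.isfinite(x0)
            & np.isfinite(x1)
            & np.isfinite(Z).all(axis=1)
        )
        return y0[keep], y1[keep], x0[keep], x1[keep], Z[keep]


@dataclass
class LmmTestResult:
    """Result of one mixed-model contrast with permutation inference."""

    name: str
    estimate: float
    t: float
    direction: str
    p_permutation: float = np.nan
    n_permutations: int = 0
    n: int = 0
    seed: int | None = None
    sigma2: float = np.nan
    tau2: float = np.nan
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Profile-ML fitter for the balanced paired random-intercept model
# ---------------------------------------------------------------------------

def _paired_ml_batch(
    dX: np.ndarray,
    dy: np.ndarray,
    mX: np.ndarray,
    my: np.ndarray,
    j: int = 0,
    tol: float = 1e-12,
    maxiter: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched ML fit of the two-block (difference / mean) Gaussian model.

    ``dX``: (B, n, p) within-pair difference design (varies over the batch),
    ``mX``: (n, p) pair-mean design (shared), ``dy``/``my``: (n,) responses.
    Returns (beta, t_j, sigma2, tau2) with tau2 truncated at zero.
    """
    B, n, p = dX.shape
    dXt = np.swapaxes(dX, -1, -2)
    A_d = np.matmul(dXt, dX)  # (B, p, p)
    b_d = np.matmul(dXt, dy[:, None])[..., 0]  # (B, p)
    A_m = mX.T @ mX  # (p, p)
    b_m = mX.T @ my  # (p,)
    s_d = np.ones(B)
    s_m = np.ones(B)
    beta = np.zeros((B, p))
    for _ in range(maxiter):
        A = A_d / s_d[:, None, None] + A_m / s_m[:, None, None]
        b = b_d / s_d[:, None] + b_m / s_m[:, None]
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        rss_d = np.square(dy - np.matmul(dX, beta[..., None])[..., 0]).sum(axis=1)
        rss_m = np.square(my - beta @ mX.T).sum(axis=1)
        new_d = rss_d / n
        new_m = rss_m / n
        pooled = (rss_d + rss_m) / (2 * n)
        boundary = new_m < new_d  # tau^2 would be negative
        new_d = np.where(boundary, pooled, new_d)
        new_m = np.where(boundary, pooled, new_m)
        floor = 1e-12 * (np.mean(dy * dy) + np.mean(my * my) + 1e-30)
        new_d = np.maximum(new_d, floor)
        new_m = np.maximum(new_m, floor)
        if np.max(np.abs(new_d - s_d) + np.abs(new_m - s_m)) < tol * (
            1.0 + np.max(new_d)
        ):
            s_d, s_m = new_d, new_m
            break
        s_d, s_m = new_d, new_m
    A = A_d / s_d[:, None, None] + A_m / s_m[:, None, None]
    var = np.linalg.inv(A)[:, j, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, beta[:, j] / np.sqrt(var), 0.0)
    sigma2 = s_d
    tau2 = (s_m - s_d) / 2.0
    return beta, t, sigma2, tau2


def _blocks(design: RepeatedMeasuresDesign):
    y0, y1, x0, x1, Z = design.arrays()
    n = y0.size
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    dy = (y1 - y0) * inv_sqrt2
    my = (y0 + y1) * inv_sqrt2
    ones = np.ones(n)
    # fixed-effect columns: [interest, covariates..., intercept]
    dX = np.column_stack([(x1 - x0) * inv_sqrt2, np.zeros_like(Z), np.zeros(n)])
    mX = np.column_stack([(x0 + x1) * inv_sqrt2, Z * np.sqrt(2.0), ones * np.sqrt(2.0)])
    return dy, my, dX, mX, n


def paired_ml_contrast(design: RepeatedMeasuresDesign) -> tuple[float, float, float, float]:
    """Profile-ML estimate and t statistic of the occasion effect.

    Returns ``(estimate, t, sigma2, tau2)``; equivalent to the ML fit of the
    random-intercept mixed model on the 2n stacked observations.
    """
    dy, my, dX, mX, _ = _blocks(design)
    beta, t, s2, t2 = _paired_ml_batch(dX[None], dy, mX, my, j=0)
    return float(beta[0, 0]), float(t[0]), float(s2[0]), float(t2[0])


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def fit_lmm(design: RepeatedMeasuresDesign) -> LmmTestResult:
    """ML fit of the random-intercept mixed model via statsmodels MixedLM.

    Falls back to pooled OLS (zero between-participant variance) when the
    mixed fit is singular, with a warning; the result is still returned.
    """
    import statsmodels.api as sm

    y0, y1, x0, x1, Z = design.arrays()
    n = y0.size
    endog = np.concatenate([y0, y1])
    exog = np.column_stack(
        [
            np.concatenate([x0, x1]),
            np.vstack([Z, Z]),
            np.ones(2 * n),
        ]
    )
    groups = np.concatenate([np.arange(n), np.arange(n)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(endog, exog, groups=groups).fit(reml=False)
        est = float(fit.params[0])
        t = float(fit.tvalues[0])
        sigma2 = float(fit.scale)
        tau2 = float(fit.cov_re.iloc[0, 0]) if hasattr(fit.cov_re, "iloc") else float(fit.cov_re[0, 0])
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(f"mixed model singular ({err}); falling back to OLS")
        ols = sm.OLS(endog, exog).fit()
        est, t, sigma2, tau2 = float(ols.params[0]), float(ols.tvalues[0]), float(ols.scale), 0.0
    return LmmTestResult(
        name="fixed_effect_of_interest",
        estimate=est,
        t=t,
        direction="two_sided",
        n=n,
        sigma2=sigma2,
        tau2=tau2,
    )


def _pvalue_from_null(t_obs: float, t_null: np.ndarray, direction: str, sampled: bool) -> float:
    if direction == "increase":
        hits = np.sum(t_null >= t_obs)
    elif direction == "decrease":
        hits = np.sum(t_null <= t_obs)
    elif direction == "two_sided":
        hits = np.sum(np.abs(t_null) >= abs(t_obs))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if sampled:
        return (1.0 + float(hits)) / (1.0 + t_null.size)
    return float(hits) / t_null.size


def permutation_test_repeated(
    design: RepeatedMeasuresDesign,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    direction: str = "two_sided",
    exhaustive: bool = False,
    name: str = "contrast",
    unit: str = "flip",
) -> LmmTestResult:
    """Within-participant occasion-flip permutation test of the LMM contrast.

    With the default ``unit="flip"`` each relabeling flips the earlier/later
    occupancy of the interest regressor for an independent subset of
    participants and refits the model; ``exhaustive=True`` enumerates all
    2^n sign patterns (identity included, so p >= 1/2^n), otherwise
    ``n_perm`` random patterns are drawn and the add-one estimator is used.
    ``unit="participant"`` instead permutes the (earlier, later) interest
    regressor pairs across participants (only meaningful when the regressor
    varies between participants, as the time-in-days regressor does).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if unit not in ("flip", "participant"):
        raise ValueError(f"unknown permutation unit {unit!r}")
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if unit == "participant":
        return _participant_permutation_test(
            design, n_perm=n_perm, seed=seed, direction=direction, name=name
        )
    dy, my, dX, mX, n = _blocks(design)
    if np.abs(dy).max() == 0.0 and np.abs(dX[:, 0]).max() > 0.0:
        # no within-pair variation at all: the occasion effect is exactly zero
        return LmmTestResult(
            name=name,
            estimate=0.0,
            t=0.0,
            direction=direction,
            p_permutation=1.0,
            n_permutations=2**n if exhaustive else n_perm,
            n=n,
        )
    beta_obs, t_obs_arr, s2, t2 = _paired_ml_batch(dX[None], dy, mX, my, j=0)
    t_obs = float(t_obs_arr[0])

    if exhaustive:
        if n > _EXHAUSTIVE_LIMIT:
            raise ValueError(f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_LIMIT}")
        codes = np.arange(2**n, dtype=np.int64)
        eps = 1.0 - 2.0 * ((codes[:, None] >> np.arange(n)) & 1)  # (2^n, n) of +-1
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        eps = rng.choice([-1.0, 1.0], size=(n_perm, n))
    dXb = np.broadcast_to(dX, (eps.shape[0], n, dX.shape[1])).copy()
    dXb[:, :, 0] = dX[:, 0] * eps
    _, t_null, _, _ = _paired_ml_batch(dXb, dy, mX, my, j=0)
    p = _pvalue_from_null(t_obs, t_null, direction, sampled=not exhaustive)
    return LmmTestResult(
        name=name,
        estimate=float(beta_obs[0, 0]),
        t=t_obs,
        direction=direction,
        p_permutation=p,
        n_permutations=int(eps.shape[0]),
        n=n,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        sigma2=float(s2[0]),
        tau2=float(t2[0]),
    )


def _participant_permutation_test(
    design: RepeatedMeasuresDesign,
    n_perm: int,
    seed,
    direction: str,
    name: str,
) -> LmmTestResult:
    """Alternative scheme: shuffle interest-regressor pairs across
    participants, refitting the model one permutation at a time."""
    y0, y1, x0, x1, Z = design.arrays()
    n = y0.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    est, t_obs, s2, t2 = paired_ml_contrast(design)
    t_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        shuffled = RepeatedMeasuresDesign(
            y_earlier=y0, y_later=y1, x_earlier=x0[perm], x_later=x1[perm], covariates=Z
        )
        t_null[b] = paired_ml_contrast(shuffled)[1]
    p = _pvalue_from_null(t_obs, t_null, direction, sampled=True)
    return LmmTestResult(
        name=name,
        estimate=est,
        t=t_obs,
        direction=direction,
        p_permutation=p,
        n_permutations=n_perm,
        n=n,
        sigma2=s2,
        tau2=t2,
    )


def _covariate_matrix(cohort: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    out = {}
    for c in cols:
        col = cohort[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            col = col.map({lev: i for i, lev in enumerate(levels)})
        out[c] = col.astype(float)
    return pd.DataFrame(out, index=cohort.index)


def stage_contrasts(
    psychophys: pd.DataFrame,
    cohort: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[LmmTestResult]:
    """The four psychophysiological contrasts: perceived stress and pulse
    under stress exposure (expected increase) and after cessation (expected
    decrease).

    ``psychophys`` is long-format (participant_id, stage, parameter, value);
    participants missing either stage of a contrast are dropped from it.
    Nuisance covariates: MS type, cognitive task load, sex, age.
    """
    ss = np.random.SeedSequence(seed)
    covs = _covariate_matrix(cohort, ("ms_type", "task_load", "sex", "age"))
    results = []
    for (param, early, late, direction), child in zip(
        STAGE_CONTRASTS, ss.spawn(len(STAGE_CONTRASTS))
    ):
        sub = psychophys[psychophys["parameter"] == param]
        wide = sub.pivot_table(
            index="participant_id", columns="stage", values="value", aggfunc="first"
        )
        if early not in wide.columns or late not in wide.columns:
            raise ValueError(f"missing stage {early}/{late} for parameter {param}")
        wide = wide[[early, late]].dropna()
        ids = wide.index
        design = RepeatedMeasuresDesign(
            y_earlier=wide[early].to_numpy(),
            y_later=wide[late].to_numpy(),
            x_earlier=np.zeros(len(ids)),
            x_later=np.ones(len(ids)),
            covariates=covs.loc[ids],
            participant_ids=ids.to_numpy(),
        )
        res = permutation_test_repeated(
            design,
            n_perm=n_perm,
            seed=np.random.default_rng(child),
            direction=direction,
            name=f"{param}_{early}_vs_{late}",
        )
        res.seed = seed
        results.append(res)
    return results


def longitudinal_change(
    outcomes: pd.DataFrame,
    scales: tuple[str, ...] = ("total", "fatigue", "lower_limb", "upper_limb", "social", "mood"),
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[LmmTestResult]:
    """Longitudinal worsening of overall HRQoL and the subscales.

    The interest regressor codes time as 0 at T0 and the follow-up delay in
    days at T1, so the estimate is a slope per day; worsening (higher
    HAQUAMS) is the positive direction.  Nuisance covariates: sex, age, MS
    type.  ``outcomes`` holds per participant ``<scale>_T0``, ``<scale>_T1``,
    ``followup_days`` and the covariates.
    """
    ss = np.random.SeedSequence(seed)
    covs = _covariate_matrix(outcomes, ("sex", "age", "ms_type"))
    results = []
    for scale, child in zip(scales, ss.spawn(len(scales))):
        c0, c1 = f"{scale}_T0", f"{scale}_T1"
        if c0 not in outcomes.columns or c1 not in outcomes.columns:
            warnings.warn(f"scale {scale!r} missing from outcome table; skipped")
            continue
        n = len(outcomes)
        design = RepeatedMeasuresDesign(
            y_earlier=outcomes[c0].to_numpy(dtype=float),
            y_later=outcomes[c1].to_numpy(dtype=float),
            x_earlier=np.zeros(n),
            x_later=outcomes["followup_days"].to_numpy(dtype=float),
            covariates=covs,
        )
        res = permutation_test_repeated(
            design,
            n_perm=n_perm,
            seed=np.random.default_rng(child),
            direction="increase",
            name=f"longitudinal_{scale}",
        )
        res.seed = seed
        results.append(res)
    return results


def results_table(results: list[LmmTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "estimate": r.estimate,
                "t": r.t,
                "direction": r.direction,
                "p_perm": r.p_permutation,
                "n_perm": r.n_permutations,
                "n": r.n,
                "seed": r.seed,
            }
            for r in results
        ]
    )
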