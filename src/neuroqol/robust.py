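"""Robust regression with permutation-based Wald inference and Bonferroni
family-wise error control.

The change in a HAQUAMS scale between baseline (T0) and follow-up (T1) is
regressed on one predictor of interest -- a clinico-demographic marker, or the
differential activity of one latent neural network -- alongside fixed nuisance
covariates.  The fit is an M-estimate (Huber psi, iteratively reweighted least
squares, MAD residual scale), chosen for its bounded sensitivity to outlying
change scores in a small cohort.  Inference on the predictor of interest uses
the Wald statistic

    W = beta_hat^2 / Var_hat(beta_hat),

with a heteroskedasticity-consistent sandwich variance, asymptotically
Chi^2(1) under the null.  Its null distribution is obtained by permutation:
the predictor-of-interest column is shuffled across participants while the
response and nuisance columns stay fixed, the model is refit and W recomputed
for each permutation, and the two-sided p-value uses the add-one estimator

    p = (1 + #{W_perm >= W_obs}) / (1 + n_perm),

which is valid at any finite number of permutations.  Across the family of
latent networks the per-test level is Bonferroni-divided (alpha / m).

Permutation loops run through a batched IRLS path.  Because every permuted
design shares its response and nuisance block and differs only in the
interest column, the normal equations are assembled from precomputed
nuisance cross-products and a handful of matrix products with small inner
dimensions, so calibration studies with millions of refits stay cheap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import PROCESSES, DifferentialActivity

#: Huber tuning constant giving 95% efficiency under Gaussian errors.
HUBER_C = 1.345
#: Normal consistency constant for the median absolute deviation.
MAD_C = 0.6745

IRLS_TOL = 1e-8
IRLS_MAXITER = 200
#: After this many IRLS iterations the MAD scale is frozen; with a fixed
#: scale the reweighting minimizes a convex loss and cannot cycle.
SCALE_FREEZE_ITER = 30

_EXHAUSTIVE_LIMIT = 8  # n! enumeration ceiling

#: The nine clinico-demographic and radiographic markers screened one at a
#: time for prognostic information on future overall HRQoL.
MARKERS: tuple[str, ...] = (
    "sex",
    "age",
    "education",
    "edss",
    "relapse_rate",
    "t2_lesion_load",
    "ms_type",
    "disease_duration",
    "gm_fraction",
)


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable designs."""


class DegenerateDesignError(DesignError):
    """Raised when the variance estimate of the tested coefficient is zero."""


# ---------------------------------------------------------------------------
# Batched Huber IRLS on designs sharing all but the interest column
# ---------------------------------------------------------------------------

def _mad_scale(resid: np.ndarray) -> np.ndarray:
    """Median absolute deviation about zero, standardized for the normal."""
    return np.median(np.abs(resid), axis=-1) / MAD_C


def huber_weights(u: np.ndarray, c: float = HUBER_C) -> np.ndarray:
    """IRLS weights of the Huber psi: 1 inside [-c, c], c/|u| outside."""
    au = np.abs(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(au > c, c / au, 1.0)
    return np.where(au == 0, 1.0, w)


class _SharedDesign:
    """Cross-product workspace for batched fits of X_b = [x_b | Z].

    ``Z`` (n, q) is the shared block (nuisance plus intercept), ``x_b``
    (B, n) the batch of interest columns, ``y`` the response -- shared
    (n,) when the interest column is permuted, or batched (B, n) for
    residual-permutation schemes.
    """

    def __init__(self, xcols: np.ndarray, Z: np.ndarray, y: np.ndarray):
        self.x = np.ascontiguousarray(xcols, dtype=float)
        self.Z = np.asarray(Z, dtype=float)
        self.y = np.asarray(y, dtype=float)
        n, q = self.Z.shape
        self.n, self.q = n, q
        self.p = q + 1
        self.Zpair = (self.Z[:, :, None] * self.Z[:, None, :]).reshape(n, q * q)
        self.y_batched = self.y.ndim == 2
        self.Zy = None if self.y_batched else self.Z * self.y[:, None]

    def normal_equations(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Assemble A = X'WX (B, p, p) and b = X'Wy (B, p)."""
        B = w.shape[0]
        x, Z, y = self.x, self.Z, self.y
        wx = w * x
        A = np.empty((B, self.p, self.p))
        A[:, 0, 0] = np.einsum("bn,bn->b", wx, x)
        cross = wx @ Z
        A[:, 0, 1:] = cross
        A[:, 1:, 0] = cross
        A[:, 1:, 1:] = (w @ self.Zpair).reshape(B, self.q, self.q)
        b = np.empty((B, self.p))
        if self.y_batched:
            b[:, 0] = np.einsum("bn,bn->b", wx, y)
            b[:, 1:] = (w * y) @ Z
        else:
            b[:, 0] = wx @ y
            b[:, 1:] = w @ self.Zy
        return A, b

    def residuals(self, beta: np.ndarray) -> np.ndarray:
        y = self.y if self.y_batched else self.y[None, :]
        return y - self.x * beta[:, :1] - beta[:, 1:] @ self.Z.T

    def subset(self, idx: np.ndarray) -> "_SharedDesign":
        sub = object.__new__(_SharedDesign)
        sub.__dict__.update(self.__dict__)
        sub.x = self.x[idx]
        if self.y_batched:
            sub.y = self.y[idx]
        return sub


def _irls_huber_shared(
    design: _SharedDesign,
    c: float = HUBER_C,
    tol: float = IRLS_TOL,
    maxiter: int = IRLS_MAXITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Huber IRLS over a batch of shared-block designs.

    Returns (beta (B, p), w (B, n), scale (B,), converged (B,)); the interest
    coefficient is beta[:, 0].
    """
    B, n = design.x.shape
    w_full = np.ones((B, n))
    A, b = design.normal_equations(w_full)
    beta = np.linalg.solve(A, b[..., None])[..., 0]  # OLS start
    scale = np.zeros(B)
    converged = np.zeros(B, dtype=bool)
    active = np.arange(B)
    d = design
    beta_a = beta
    frozen = None
    for it in range(maxiter):
        r = d.residuals(beta_a)
        if frozen is None:
            s = _mad_scale(r)
            if it == SCALE_FREEZE_ITER:
                frozen = s
        else:
            s = frozen
        degenerate = s < 1e-12
        s_safe = np.where(degenerate, 1.0, s)
        wa = huber_weights(r / s_safe[:, None], c)
        wa[degenerate] = 1.0
        A, b = d.normal_equations(wa)
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        done = (np.abs(beta_new - beta_a).max(axis=1) < tol) | degenerate
        beta[active] = beta_new
        w_full[active] = wa
        scale[active] = s
        if done.any():
            converged[active[done]] = True
            keep = ~done
            if not keep.any():
                break
            active = active[keep]
            d = design.subset(active)
            beta_a = beta_new[keep]
            if frozen is not None:
                frozen = frozen[keep]
        else:
            beta_a = beta_new
    return beta, w_full, scale, converged


def _sandwich_wald_shared(
    design: _SharedDesign, beta: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched sandwich Wald statistic for the interest coefficient.

    Bread is (X'WX)^-1, meat is sum_i (w_i r_i)^2 x_i x_i'; in the
    equal-weights limit this is the HC0 heteroskedasticity-consistent
    covariance of ordinary least squares.
    """
    B = beta.shape[0]
    r = design.residuals(beta)
    A, _ = design.normal_equations(w)
    u2 = np.square(w * r)
    x, Z = design.x, design.Z
    M = np.empty_like(A)
    u2x = u2 * x
    M[:, 0, 0] = np.einsum("bn,bn->b", u2x, x)
    cross = u2x @ Z
    M[:, 0, 1:] = cross
    M[:, 1:, 0] = cross
    M[:, 1:, 1:] = (u2 @ design.Zpair).reshape(B, design.q, design.q)
    Ainv = np.linalg.inv(A)
    V = np.matmul(np.matmul(Ainv, M), Ainv)
    var_j = V[:, 0, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(var_j > 0, beta[:, 0] ** 2 / var_j, np.inf)
    wald = np.where((var_j <= 0) & (beta[:, 0] == 0), 0.0, wald)
    return wald, var_j


def _fit_and_wald(
    xcols: np.ndarray, Z: np.ndarray, y: np.ndarray, c: float = HUBER_C
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Fit the batch and return (beta, wald, var, diagnostics)."""
    design = _SharedDesign(xcols, Z, y)
    beta, w, scale, conv = _irls_huber_shared(design, c=c)
    wald, var = _sandwich_wald_shared(design, beta, w)
    return beta, wald, var, {"weights": w, "scale": scale, "converged": conv}


# ---------------------------------------------------------------------------
# Public fitting / testing surface
# ---------------------------------------------------------------------------

@dataclass
class RegressionDesign:
    """One robust-regression analysis: response, predictor of interest and
    fixed nuisance covariates (an intercept is always appended)."""

    response: pd.Series | np.ndarray
    predictor: pd.Series | np.ndarray
    nuisance: pd.DataFrame | np.ndarray | None = None
    participant_ids: pd.Index | None = None

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (y, x_interest, Z) after listwise deletion; ``Z`` is the
        nuisance block with the intercept as its last column."""
        y = np.asarray(self.response, dtype=float)
        x = np.asarray(self.predictor, dtype=float)
        if self.nuisance is None:
            N = np.empty((y.size, 0))
        else:
            N = np.asarray(self.nuisance, dtype=float)
            if N.ndim == 1:
                N = N[:, None]
        if not (y.shape[0] == x.shape[0] == N.shape[0]):
            raise DesignError("response, predictor and nuisance lengths differ")
        keep = np.isfinite(y) & np.isfinite(x) & np.isfinite(N).all(axis=1)
        y, x, N = y[keep], x[keep], N[keep]
        Z = np.column_stack([N, np.ones(y.size)])
        n, p = y.size, Z.shape[1] + 1
        if n <= p:
            raise DesignError(f"n={n} observations for p={p} coefficients")
        if np.ptp(x) == 0:
            raise DegenerateDesignError("predictor of interest has zero variance")
        if np.linalg.matrix_rank(np.column_stack([x, Z])) < p:
            raise DesignError("design matrix is rank deficient")
        return y, x, Z


@dataclass
class RobustFitResult:
    """Robust fit plus permutation inference for one predictor of interest.

    ``coefficients[0]`` is the predictor of interest, followed by the
    nuisance coefficients and the intercept.
    """

    coefficients: np.ndarray
    scale: float
    converged: bool
    wald_statistic: float = np.nan
    t_equivalent: float = np.nan
    p_permutation: float = np.nan
    p_fwe: float = np.nan
    n_permutations: int = 0
    n: int = 0
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def estimate(self) -> float:
        return float(self.coefficients[0])


def robust_fit(design: RegressionDesign, c: float = HUBER_C) -> RobustFitResult:
    """Huber M-estimate of the regression coefficients (IRLS, MAD scale)."""
    y, x, Z = design.matrices()
    beta, wald, var, diag = _fit_and_wald(x[None], Z, y, c=c)
    return RobustFitResult(
        coefficients=beta[0],
        scale=float(diag["scale"][0]),
        converged=bool(diag["converged"][0]),
        n=y.size,
        extra={"weights": diag["weights"][0]},
    )


def wald_statistic(design: RegressionDesign, c: float = HUBER_C) -> float:
    """Sandwich Wald statistic for the predictor of interest."""
    y, x, Z = design.matrices()
    _, wald, var, _ = _fit_and_wald(x[None], Z, y, c=c)
    if var[0] <= 0 or not np.isfinite(wald[0]):
        raise DegenerateDesignError("zero sandwich variance for tested coefficient")
    return float(wald[0])


def permutation_wald_pvalue(
    y: np.ndarray,
    x: np.ndarray,
    Z: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool = False,
    c: float = HUBER_C,
    scheme: str = "interest",
) -> tuple[float, float, float]:
    """Low-level permutation test on prepared arrays.

    With the default ``scheme="interest"`` the interest column ``x`` is
    permuted across rows (response and nuisance block ``Z`` fixed), the
    studentized-statistic construction of the robust permutation method.
    ``scheme="freedman_lane"`` instead permutes the residuals of the
    nuisance-only robust fit and adds them back to its fitted values,
    refitting the full model on each reconstructed response.  Either way the
    Huber regression is refit for every permutation in one batched IRLS pass
    and Wald statistics are compared.  With ``exhaustive=True`` all n!
    arrangements (identity included) are enumerated and
    p = #{W >= W_obs} / n!.

    Returns ``(p, W_obs, beta_obs)``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n < 2:
        raise DesignError("need at least two observations to permute")
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    beta0, w_obs_arr, var0, _ = _fit_and_wald(x[None], Z, y, c=c)
    if var0[0] <= 0 or not np.isfinite(w_obs_arr[0]):
        raise DegenerateDesignError("zero sandwich variance for tested coefficient")
    w_obs = float(w_obs_arr[0])

    if scheme not in ("interest", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if exhaustive:
        if n > _EXHAUSTIVE_LIMIT:
            raise ValueError(f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_LIMIT}")
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
    if scheme == "interest":
        _, wald, _, _ = _fit_and_wald(x[perms], Z, y, c=c)
    else:
        # Freedman-Lane: permute residuals of the nuisance-only robust fit
        # (the reduced design reuses the shared-block fitter with Z's first
        # column in the interest slot)
        reduced = _SharedDesign(Z[:, 0][None, :], Z[:, 1:], y)
        gamma, _, _, _ = _irls_huber_shared(reduced, c=c)
        fitted = Z @ gamma[0]
        resid = y - fitted
        y_star = fitted[None, :] + resid[perms]
        B = perms.shape[0]
        xb = np.broadcast_to(x, (B, n))
        _, wald, _, _ = _fit_and_wald(xb, Z, y_star, c=c)
    wald = np.nan_to_num(wald, nan=np.inf)  # degenerate permutation = extreme
    if exhaustive:
        p = float(np.mean(wald >= w_obs))
    else:
        p = (1.0 + int(np.sum(wald >= w_obs))) / (1.0 + perms.shape[0])
    return p, w_obs, float(beta0[0, 0])


def permutation_pvalue(
    design: RegressionDesign,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool = False,
    c: float = HUBER_C,
) -> RobustFitResult:
    """Robust fit + two-sided permutation p-value for one design."""
    y, x, Z = design.matrices()
    fit = robust_fit(design, c=c)
    p, w_obs, _ = permutation_wald_pvalue(
        y, x, Z, n_perm=n_perm, seed=seed, exhaustive=exhaustive, c=c
    )
    fit.wald_statistic = w_obs
    fit.t_equivalent = math.copysign(math.sqrt(w_obs), fit.coefficients[0])
    fit.p_permutation = p
    fit.n_permutations = math.factorial(y.size) if exhaustive else n_perm
    fit.seed = seed if isinstance(seed, (int, np.integer)) else None
    return fit


def bonferroni_threshold(alpha_fwe: float, m: int) -> float:
    """Per-test alpha controlling family-wise error over ``m`` tests."""
    if not 0 < alpha_fwe < 1:
        raise ValueError("alpha_fwe must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha_fwe / m


def bonferroni_threshold_display(alpha_fwe: float, m: int) -> float:
    """The per-test alpha rounded to 4 decimals for reporting."""
    return round(bonferroni_threshold(alpha_fwe, m), 4)


def fwe_adjust(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, min(1, m * p)."""
    return min(1.0, m * p)


def _encode(col: pd.Series) -> pd.Series:
    """Numeric encoding for binary categorical covariates (e.g. RRMS/SPMS)."""
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.dropna().unique())
        return col.map({lev: i for i, lev in enumerate(levels)}).astype(float)
    return col.astype(float)


def screen_markers(
    outcomes: pd.DataFrame,
    markers: tuple[str, ...] = MARKERS,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen clinico-demographic markers for prognostic information on the
    change in overall HRQoL, one robust regression per marker.

    ``outcomes`` must hold per participant ``delta_total``, ``total_T0``,
    ``followup_days`` and the marker columns.  Nuisance covariates are the T0
    total score and the follow-up interval (plus intercept).  Significance is
    evaluated two-sided at ``alpha`` without multiplicity correction: this is
    a screening step whose hits become covariates downstream.
    """
    missing = [m for m in markers if m not in outcomes.columns]
    if missing:
        raise DesignError(f"marker columns missing from table: {missing}")
    ss = np.random.SeedSequence(seed)
    rows = []
    for marker, child in zip(markers, ss.spawn(len(markers))):
        design = RegressionDesign(
            response=outcomes["delta_total"],
            predictor=_encode(outcomes[marker]),
            nuisance=outcomes[["total_T0", "followup_days"]],
        )
        res = permutation_pvalue(
            design, n_perm=n_perm, seed=np.random.default_rng(child)
        )
        rows.append(
            {
                "marker": marker,
                "estimate": res.estimate,
                "wald": res.wald_statistic,
                "t_equivalent": res.t_equivalent,
                "p_perm": res.p_permutation,
                "significant": res.p_permutation < alpha,
                "n": res.n,
                "n_perm": res.n_permutations,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def _family_tests(
    y: np.ndarray,
    Z: np.ndarray,
    predictors: np.ndarray,
    n_perm: int,
    children: list,
    c: float = HUBER_C,
    max_batch: int = 120_000,
) -> list[dict]:
    """Permutation Wald tests for every predictor column of one family.

    ``predictors`` is (n, m); all columns share the response ``y`` and
    nuisance block ``Z`` (rows already listwise-complete, intercept
    included).  Each column's permutations come from its own seeded
    generator, so results match the column-at-a-time path exactly.  Columns
    are concatenated into large batches (chunked at ``max_batch`` designs).
    """
    n, m = predictors.shape
    results: list[dict] = [{} for _ in range(m)]
    per_net = n_perm + 1  # observed + permutations
    chunk_nets = max(1, max_batch // per_net)
    for start in range(0, m, chunk_nets):
        cols = range(start, min(start + chunk_nets, m))
        blocks = []
        for k in cols:
            x = predictors[:, k]
            rng = np.random.default_rng(children[k])
            perms = np.argsort(rng.random((n_perm, n)), axis=1)
            blocks.append(np.vstack([x[None, :], x[perms]]))
        xb = np.concatenate(blocks, axis=0)
        beta, wald, var, diag = _fit_and_wald(xb, Z, y, c=c)
        for i, k in enumerate(cols):
            sl = slice(i * per_net, (i + 1) * per_net)
            w_obs = wald[sl][0]
            w_null = np.nan_to_num(wald[sl][1:], nan=np.inf)
            if var[sl][0] <= 0 or not np.isfinite(w_obs):
                results[k] = {"degenerate": True}
                continue
            results[k] = {
                "degenerate": False,
                "estimate": float(beta[sl][0, 0]),
                "wald": float(w_obs),
                "p_perm": (1.0 + int(np.sum(w_null >= w_obs))) / (1.0 + n_perm),
                "converged": bool(diag["converged"][sl][0]),
            }
    return results


def predict_hrql_from_networks(
    differentials: DifferentialActivity,
    outcomes: pd.DataFrame,
    scales: tuple[str, ...] = ("total",),
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha_fwe_primary: float = 0.05,
    alpha_fwe_subscale: float = 0.1,
    c: float = HUBER_C,
) -> pd.DataFrame:
    """The key analysis: for each neural process (stress exposure, stress
    cessation), each latent network and each HAQUAMS scale, robustly regress
    the scale's change score on the network's differential activity.

    Nuisance covariates: the scale's T0 score, follow-up interval in days,
    cognitive task load and disease type (plus intercept).  Permutation
    p-values are Bonferroni-corrected within each process x scale family
    (m = number of networks); the ``significant`` flag uses
    ``alpha_fwe_primary`` for the total score and ``alpha_fwe_subscale`` for
    subscales.  Participants with a missing differential (e.g. no baseline-2
    scan) are dropped listwise from the affected process only.  A
    zero-variance differential column is reported as non-testable.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for process in PROCESSES:
        plane = differentials.plane(process)
        networks = list(plane.columns)
        m = len(networks)
        for scale in scales:
            alpha_fam = alpha_fwe_primary if scale == "total" else alpha_fwe_subscale
            fam = outcomes.loc[plane.index]
            nuisance = pd.DataFrame(
                {
                    "t0_score": fam[f"{scale}_T0"].astype(float),
                    "followup_days": fam["followup_days"].astype(float),
                    "task_load": fam["task_load"].astype(float),
                    "ms_type": _encode(fam["ms_type"]),
                },
                index=fam.index,
            )
            children = ss.spawn(m)
            y_all = fam[f"delta_{scale}"].to_numpy(dtype=float)
            N_all = nuisance.to_numpy(dtype=float)
            P_all = plane.to_numpy(dtype=float)
            keep = (
                np.isfinite(y_all)
                & np.isfinite(N_all).all(axis=1)
                & np.isfinite(P_all).all(axis=1)
            )
            y_f, N_f, P_f = y_all[keep], N_all[keep], P_all[keep]
            n_eff = int(keep.sum())
            Z_f = np.column_stack([N_f, np.ones(n_eff)])
            testable = np.ptp(P_f, axis=0) > 0 if n_eff else np.zeros(m, dtype=bool)
            fam_results: list[dict] = [{"degenerate": True}] * m
            if testable.any() and n_eff > Z_f.shape[1] + 2:
                tested = _family_tests(
                    y_f,
                    Z_f,
                    P_f[:, testable],
                    n_perm,
                    [ch for ch, t in zip(children, testable) if t],
                    c=c,
                )
                it = iter(tested)
                fam_results = [
                    next(it) if t else {"degenerate": True} for t in testable
                ]
            for network, res in zip(networks, fam_results):
                row = {
                    "process": process,
                    "network": network,
                    "scale": scale,
                    "n_perm": n_perm,
                    "seed": seed,
                    "alpha_fwe": alpha_fam,
                    "m": m,
                }
                if res.get("degenerate", True):
                    row.update(
                        {
                            "testable": False,
                            "estimate": np.nan,
                            "wald": np.nan,
                            "t_equivalent": np.nan,
                            "p_perm": np.nan,
                            "p_fwe": np.nan,
                            "n": np.nan,
                            "significant": False,
                        }
                    )
                else:
                    p_fwe = fwe_adjust(res["p_perm"], m)
                    row.update(
                        {
                            "testable": True,
                            "estimate": res["estimate"],
                            "wald": res["wald"],
                            "t_equivalent": math.copysign(
                                math.sqrt(res["wald"]), res["estimate"]
                            ),
                            "p_perm": res["p_perm"],
                            "p_fwe": p_fwe,
                            "n": n_eff,
                            "significant": p_fwe < alpha_fam,
                        }
                    )
                rows.append(row)
    return pd.DataFrame(rows)
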