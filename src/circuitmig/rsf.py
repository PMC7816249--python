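"""Used-available resource selection analysis.

Observed migration fixes (used, response 1) are contrasted with random
points drawn uniformly over the study area (available, response 0; 20 per
used point by default) in a logistic regression with logit link.  The
exponential road-decay parameter alpha is chosen by an AICc scan over a
fixed candidate grid; the covariate structure by AICc over the factorial
set of covariate-group combinations; collinearity is screened with
variance inflation factors; predictive skill with k-fold binned Spearman
validation; and road response curves with a parametric bootstrap of the
coefficient sampling distribution.

Random intercepts for animal and for year-within-animal are available via
an in-package Laplace approximation to the marginal binomial likelihood;
when the variance estimates sit on the zero boundary the fit coincides
with the plain fixed-effects logistic fit.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, sparse, stats

from .covariates import CovariateStack, decay_from_distance
from .raster import RasterGrid

__all__ = [
    "RSFFit",
    "SeparationError",
    "DEFAULT_ALPHA_GRID",
    "COVARIATE_GROUPS",
    "aicc",
    "sample_availability",
    "build_table",
    "fit_rsf",
    "candidate_model_set",
    "vif",
    "select_decay_alpha",
    "select_model",
    "predict_suitability",
    "kfold_validate",
    "bootstrap_response",
]

#: alpha candidates (km): every km 1-20, every 5 km 25-50, every 10 km
#: 60-100, every 50 km 150-350 -- 36 values in total.
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(
    list(range(1, 21)) + list(range(25, 51, 5)) + list(range(60, 101, 10))
    + list(range(150, 351, 50))
)

#: covariate groups entering the factorial candidate set; land cover enters
#: as one group of three indicator columns against the open reference class.
COVARIATE_GROUPS: dict[str, tuple[str, ...]] = {
    "ruggedness": ("ruggedness",),
    "river": ("river",),
    "roads": ("road_decay",),
    "landcover": ("dense", "burned", "coastal"),
}


class SeparationError(RuntimeError):
    """Complete separation or rank deficiency in the design matrix."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# -- availability sampling ----------------------------------------------


def sample_availability(
    study_area: tuple[float, float, float, float],
    n_used: int,
    ratio: int = 20,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Uniform random available points, ``ratio`` per used location."""
    if n_used < 1:
        raise ValueError("need at least one used point")
    if ratio < 1:
        raise ValueError("availability ratio must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    xmin, ymin, xmax, ymax = study_area
    n = n_used * ratio
    xs = rng.uniform(xmin, xmax, n)
    ys = rng.uniform(ymin, ymax, n)
    return np.column_stack([xs, ys])


def build_table(
    stack: CovariateStack,
    used: pd.DataFrame,
    study_area: tuple[float, float, float, float] | None = None,
    ratio: int = 20,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Assemble the used-available design table.

    ``used`` needs columns x_km, y_km and optionally animal_id, year.
    Available rows share the pooled covariate extraction and carry
    animal_id/year NA.
    """
    if study_area is None:
        study_area = stack.grid.extent
    avail_xy = sample_availability(study_area, len(used), ratio=ratio, rng=rng)
    u = stack.covariates_at(used["x_km"].to_numpy(), used["y_km"].to_numpy())
    u.insert(0, "response", 1)
    u["x_km"] = used["x_km"].to_numpy()
    u["y_km"] = used["y_km"].to_numpy()
    u["animal_id"] = used.get("animal_id", pd.Series(["?"] * len(used))).to_numpy()
    u["year"] = used.get("year", pd.Series([0] * len(used))).to_numpy()
    a = stack.covariates_at(avail_xy[:, 0], avail_xy[:, 1])
    a.insert(0, "response", 0)
    a["x_km"] = avail_xy[:, 0]
    a["y_km"] = avail_xy[:, 1]
    # available points inherit the animal-year of their used point so the
    # grouping structure covers both response classes
    a["animal_id"] = np.repeat(u["animal_id"].to_numpy(), ratio)
    a["year"] = np.repeat(u["year"].to_numpy(), ratio)
    table = pd.concat([u, a], ignore_index=True)
    return table.dropna(subset=["ruggedness", "river", "road_decay"]).reset_index(
        drop=True
    )


# -- fitting -------------------------------------------------------------


@dataclass
class RSFFit:
    """A fitted selection model.

    ``params``/``bse`` are indexed by term name ("intercept" first);
    ``random_variances`` holds the estimated random-intercept variances
    (empty for a pure fixed-effects fit).
    """

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    k: int
    formula: tuple[str, ...]
    converged: bool = True
    random_variances: dict[str, float] = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        if not self.converged:
            raise RuntimeError("AICc withheld: fit did not converge")
        return aicc(self.loglik, self.k, self.n)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "cov": self.cov.to_dict(),
            "loglik": self.loglik,
            "n": self.n,
            "k": self.k,
            "formula": list(self.formula),
            "converged": self.converged,
            "random_variances": self.random_variances,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RSFFit":
        d = json.loads(Path(path).read_text())
        names = ["intercept"] + list(d["formula"])
        return cls(
            params=pd.Series(d["params"]).reindex(names),
            bse=pd.Series(d["bse"]).reindex(names),
            cov=pd.DataFrame(d["cov"]).reindex(index=names, columns=names),
            loglik=d["loglik"],
            n=d["n"],
            k=d["k"],
            formula=tuple(d["formula"]),
            converged=d["converged"],
            random_variances=d["random_variances"],
        )


def _design(table: pd.DataFrame, formula) -> tuple[np.ndarray, list[str]]:
    cols = list(formula)
    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(float) for c in cols])
    return X, ["intercept"] + cols


def _check_design(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SeparationError(
            f"design matrix rank-deficient (columns {names}); remove "
            "duplicated or constant covariates"
        )


def fit_rsf(
    table: pd.DataFrame,
    formula=("ruggedness", "river", "road_decay", "dense", "burned", "coastal"),
    random_effects: bool = False,
) -> RSFFit:
    """Fit the used-available logistic model.

    With ``random_effects`` the binomial likelihood is marginalised over
    random intercepts for animal and year-within-animal by a Laplace
    approximation; otherwise a plain GLM fit.  ``k`` counts fixed
    coefficients plus variance components, for AICc.
    """
    y = table["response"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("response must contain both used and available rows")
    X, names = _design(table, formula)
    _check_design(X, names)
    if random_effects:
        return _fit_glmm_laplace(table, y, X, names, formula)

    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
        ) as err:
            raise SeparationError(f"complete separation: {err}") from err
    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    # scale-invariant divergence check: a coefficient's contribution to the
    # linear predictor beyond ~30 logits signals separation, not selection
    scales = np.array([1.0] + [np.std(X[:, j]) for j in range(1, X.shape[1])])
    scales[0] = 0.0  # the intercept alone cannot separate
    if not np.isfinite(res.bse).all() or np.max(np.abs(res.params * scales)) > 30:
        raise SeparationError("complete separation: coefficients diverged")
    return RSFFit(
        params=params,
        bse=bse,
        cov=cov,
        loglik=float(res.llf),
        n=len(y),
        k=X.shape[1],
        formula=tuple(formula),
        converged=bool(res.converged),
    )


def _group_codes(values) -> np.ndarray:
    _, codes = np.unique(np.asarray(values, dtype=object).astype(str), return_inverse=True)
    return codes


def _fit_glmm_laplace(table, y, X, names, formula) -> RSFFit:
    """Laplace-approximated logistic fit with nested random intercepts.

    Random structure: one intercept per animal plus one per animal-year
    (year nested within animal); every row, used or available, loads on its
    animal's effects.
    """
    p = X.shape[1]
    a_codes = _group_codes(table["animal_id"].to_numpy())
    ay_codes = _group_codes(
        (table["animal_id"].astype(str) + ":" + table["year"].astype(str)).to_numpy()
    )
    n_a = a_codes.max() + 1
    n_ay = ay_codes.max() + 1
    q = n_a + n_ay

    rows = np.arange(len(y))
    Z = sparse.coo_matrix(
        (
            np.ones(2 * len(rows)),
            (
                np.concatenate([rows, rows]),
                np.concatenate([a_codes, n_a + ay_codes]),
            ),
        ),
        shape=(len(y), q),
    ).tocsr()
    Xs = sparse.csr_matrix(X)
    A = sparse.hstack([Xs, Z]).tocsr()

    def inner_mode(pen_diag, beta_u0):
        """Penalized-likelihood Newton for (beta, u) at fixed variances."""
        theta = beta_u0.copy()
        P = sparse.diags(pen_diag)
        for _ in range(100):
            eta = A @ theta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1 - mu) + 1e-12
            grad = A.T @ (y - mu) - P @ theta
            H = (A.T @ sparse.diags(w) @ A + P).tocsc()
            step = sparse.linalg.spsolve(H, grad)
            theta = theta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        return theta, H

    def loglik_binom(theta):
        eta = A @ theta
        return float(np.sum(y * eta - np.log1p(np.exp(eta))))

    def neg_marginal(log_sd):
        sd_a, sd_ay = np.exp(log_sd)
        pen = np.concatenate(
            [np.zeros(p), np.full(n_a, 1 / sd_a**2), np.full(n_ay, 1 / sd_ay**2)]
        )
        theta, H = inner_mode(pen, np.zeros(p + q))
        u = theta[p:]
        pen_u = pen[p:]
        ll = loglik_binom(theta) - 0.5 * np.sum(pen_u * u**2)
        Huu = H[p:, p:].toarray()
        D = np.diag(1.0 / pen_u)
        sign, logdet = np.linalg.slogdet(D @ Huu)
        if sign <= 0:
            return 1e12
        return -(ll - 0.5 * logdet)

    res = optimize.minimize(
        neg_marginal, x0=np.log([0.5, 0.5]), method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200},
    )
    sd_a, sd_ay = np.exp(res.x)
    boundary = max(sd_a, sd_ay) < 1e-3
    if boundary:
        fixed = fit_rsf(table, formula, random_effects=False)
        fixed.random_variances = {"animal": 0.0, "year_in_animal": 0.0}
        fixed.k = p + 2
        return fixed

    pen = np.concatenate(
        [np.zeros(p), np.full(n_a, 1 / sd_a**2), np.full(n_ay, 1 / sd_ay**2)]
    )
    theta, H = inner_mode(pen, np.zeros(p + q))
    cov_full = np.linalg.inv(H.toarray())
    cov_beta = cov_full[:p, :p]
    params = pd.Series(theta[:p], index=names)
    bse = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
    return RSFFit(
        params=params,
        bse=bse,
        cov=pd.DataFrame(cov_beta, index=names, columns=names),
        loglik=-res.fun,
        n=len(y),
        k=p + 2,
        formula=tuple(formula),
        converged=bool(res.success),
        random_variances={"animal": sd_a**2, "year_in_animal": sd_ay**2},
    )


# -- model selection -----------------------------------------------------


def candidate_model_set(groups: dict[str, tuple[str, ...]] | None = None):
    """All 2^g factorial combinations of covariate groups.

    The empty combination is the intercept-only model; with the default
    four groups this yields 16 candidate formulas.
    """
    groups = COVARIATE_GROUPS if groups is None else groups
    keys = list(groups)
    out = []
    for r in range(len(keys) + 1):
        for combo in itertools.combinations(keys, r):
            cols: tuple[str, ...] = tuple(
                c for key in combo for c in groups[key]
            )
            out.append(cols)
    return out


def _selection_table(entries: list[tuple[str, float]]) -> pd.DataFrame:
    df = pd.DataFrame(entries, columns=["label", "aicc"]).sort_values(
        "aicc", kind="mergesort", ignore_index=True
    )
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    rel = np.exp(-0.5 * df["delta_aicc"])
    df["akaike_weight"] = rel / rel.sum()
    return df


def select_decay_alpha(
    table: pd.DataFrame,
    candidates=None,
    include_linear: bool = True,
) -> pd.DataFrame:
    """AICc scan over road-decay alpha candidates plus a linear model.

    Each candidate fits a univariate logistic model whose road covariate is
    ``exp(-alpha/d)`` built from the table's ``road_distance_km`` column;
    the linear candidate uses raw distance.  Failed candidates are dropped
    with a warning.
    """
    candidates = DEFAULT_ALPHA_GRID if candidates is None else tuple(candidates)
    if len(candidates) + int(include_linear) < 1:
        raise ValueError("need at least one candidate model")
    d = table["road_distance_km"].to_numpy(float)
    entries = []
    work = table[["response"]].copy()
    for alpha in candidates:
        work["road_decay"] = decay_from_distance(d, float(alpha))
        try:
            fit = fit_rsf(work, formula=("road_decay",))
            entries.append((f"alpha={alpha:g}", fit.aicc))
        except (SeparationError, RuntimeError) as err:
            warnings.warn(f"alpha={alpha:g} dropped: {err}")
    if include_linear:
        work["road_distance"] = d
        try:
            fit = fit_rsf(work, formula=("road_distance",))
            entries.append(("linear", fit.aicc))
        except (SeparationError, RuntimeError) as err:
            warnings.warn(f"linear distance model dropped: {err}")
    if not entries:
        raise RuntimeError("every decay candidate failed to fit")
    return _selection_table(entries)


def best_alpha(selection: pd.DataFrame) -> float | None:
    """Winning alpha of a decay scan (None if the linear model won)."""
    label = selection["label"].iloc[0]
    return None if label == "linear" else float(label.split("=")[1])


def select_model(
    table: pd.DataFrame,
    formulas=None,
    random_effects: bool = False,
) -> pd.DataFrame:
    """AICc ranking over a candidate formula set (factorial by default)."""
    formulas = candidate_model_set() if formulas is None else formulas
    entries = []
    for cols in formulas:
        label = " + ".join(cols) if cols else "intercept-only"
        try:
            fit = fit_rsf(table, formula=cols, random_effects=random_effects)
            entries.append((label, fit.aicc))
        except (SeparationError, RuntimeError) as err:
            warnings.warn(f"model {label!r} dropped: {err}")
    return _selection_table(entries)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, one per column.

    VIF_j = 1 / (1 - R^2_j) from regressing column j (with intercept) on
    the remaining columns; perfectly collinear columns report inf.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least two columns")
    out = {}
    for j, col in enumerate(cols):
        yj = design[col].to_numpy(float)
        if np.allclose(yj, yj[0]):
            raise ValueError(f"column {col!r} is constant")
        Xj = np.column_stack(
            [np.ones(len(design))]
            + [design[c].to_numpy(float) for c in cols if c != col]
        )
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# -- prediction and validation ------------------------------------------


def predict_suitability(fit: RSFFit, stack: CovariateStack) -> RasterGrid:
    """Relative habitat suitability raster hs in (0, 1].

    ``w = exp(fixed-effect linear predictor without intercept)`` cell by
    cell, max-normalised so the best cell scores exactly 1.  The intercept
    only reflects the used:available ratio and random effects are
    individual-level, so neither enters the map.
    """
    layers = {
        "ruggedness": stack.ruggedness_z.data,
        "river": stack.river.data,
        "road_decay": stack.road_decay.data,
        "dense": (stack.landcover.data == 1).astype(float),
        "burned": (stack.landcover.data == 2).astype(float),
        "coastal": (stack.landcover.data == 3).astype(float),
    }
    lp = np.zeros(stack.grid.shape)
    for name in fit.formula:
        if name not in layers:
            raise KeyError(f"no raster layer for coefficient {name!r}")
        lp = lp + fit.params[name] * layers[name]
    valid = stack.grid.valid & stack.landcover.valid & np.isfinite(lp)
    w = np.where(valid, np.exp(lp), np.nan)
    wmax = np.nanmax(w)
    if not np.isfinite(wmax) or wmax <= 0:
        raise ValueError("non-finite linear predictor over the whole grid")
    return stack.grid.like(w / wmax)


def _binned_spearman(
    scores_used: np.ndarray,
    scores_area: np.ndarray,
    bins: int,
) -> float:
    """Area-adjusted used-frequency rank correlation over score bins."""
    lo = min(scores_area.min(), scores_used.min())
    hi = max(scores_area.max(), scores_used.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    used_counts, _ = np.histogram(scores_used, bins=edges)
    area_counts, _ = np.histogram(scores_area, bins=edges)
    keep = area_counts > 0
    if keep.sum() < 2:
        warnings.warn("fewer than two non-empty bins; rho undefined, using 0")
        return 0.0
    freq = used_counts[keep] / area_counts[keep]
    freq = freq / freq.sum() if freq.sum() > 0 else freq
    rho, _ = stats.spearmanr(np.arange(bins)[keep], freq)
    return float(rho) if np.isfinite(rho) else 0.0


def kfold_validate(
    table: pd.DataFrame,
    formula,
    k: int = 10,
    bins: int = 10,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean Spearman rho of k-fold used-point validation.

    Used rows are split into k folds; each fold's model is trained on the
    other folds (plus all available rows), withheld used points are scored,
    and the area-adjusted frequency of used points across equal-interval
    score bins is rank-correlated with bin order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    used_idx = np.flatnonzero(table["response"] == 1)
    avail = table[table["response"] == 0]
    if len(used_idx) < k:
        raise ValueError("fewer used points than folds")
    perm = rng.permutation(used_idx)
    folds = np.array_split(perm, k)
    rhos = []
    cols = list(formula)
    for fold in folds:
        test = table.loc[fold]
        train = pd.concat([table.loc[np.setdiff1d(perm, fold)], avail])
        fit = fit_rsf(train, formula=cols)
        beta = fit.params[cols].to_numpy()
        s_test = test[cols].to_numpy(float) @ beta
        s_area = avail[cols].to_numpy(float) @ beta
        rhos.append(_binned_spearman(s_test, s_area, bins))
    return float(np.mean(rhos))


def bootstrap_response(
    fit: RSFFit,
    alpha: float,
    n_boot: int = 500,
    seed: int | None = 0,
    distances_km: np.ndarray | None = None,
    conditioning: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Road-distance response curve with bootstrap mean and 95% CI.

    Coefficient vectors are drawn from the multivariate normal implied by
    the fit's estimates and covariance (a parametric bootstrap of the
    sampling distribution rather than a refit per resample); all other
    covariates are held at the supplied conditioning values (default:
    ruggedness at 0 = its standardized mean, river 0, open land cover).
    """
    if distances_km is None:
        distances_km = np.linspace(0.5, 300.0, 120)
    cond = {c: 0.0 for c in fit.formula}
    cond.update(conditioning or {})
    names = list(fit.params.index)
    cov = fit.cov.to_numpy()
    try:
        np.linalg.cholesky(cov + 1e-15 * np.eye(len(cov)))
    except np.linalg.LinAlgError as err:
        raise ValueError("coefficient covariance not positive definite") from err
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        fit.params.to_numpy(), cov, size=n_boot, method="cholesky"
    )
    decay = decay_from_distance(np.asarray(distances_km, float), alpha)
    X = np.zeros((len(distances_km), len(names)))
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        X[:, j] = decay if name == "road_decay" else cond.get(name, 0.0)
    lp = X @ draws.T  # (grid, n_boot), intercept omitted: relative selection
    w = np.exp(np.clip(lp, -700.0, 700.0))
    return pd.DataFrame(
        {
            "distance_km": distances_km,
            "mean": w.mean(axis=1),
            "ci_low": np.percentile(w, 2.5, axis=1),
            "ci_high": np.percentile(w, 97.5, axis=1),
            "plugin": np.exp(
                X @ fit.params.to_numpy()
            ),
        }
    )
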