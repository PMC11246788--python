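"""Penalized-spline phenology models with grouped random intercepts.

Median BBCH phenophase (treated as a quasi-continuous response) is modelled
as a smooth function of a single seasonal covariate — day of year (DOY),
days from snowmelt (DFSM) or growing degree days (GDD) — with plot and year
as random effects:

    phase_ij = alpha + f(x_ij) + b_plot(i) + b_year(j) + eps_ij

``f`` is a cubic B-spline with an integrated-squared-second-derivative
penalty, so the infinite-smoothing limit is exactly the straight-line fit;
the random effects are penalized (ridge) group intercepts, the standard
mixed-model-as-penalty representation.  All smoothing parameters are chosen
jointly by generalized cross-validation (GCV).  Candidate predictors are
screened for collinearity first (they are all time-driven and typically
correlate at |r| > 0.9, which is why single-predictor models are compared by
AIC rather than entered together).

The same machinery fits ecosystem greenness (GCC) as an additive combination
of per-species phenophase smooths, and supports space-for-time transfer:
a fit trained at the late-snowmelt site predicts phenophase progression at
the early site from that site's own GDD axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

PREDICTORS = ("gdd", "dfsm", "doy")        # also the AIC tie-break priority
CORRELATION_FLAG = 0.90
DEFAULT_BASIS_DIM = 8

# 2-point Gauss-Legendre nodes on [0, 1]; exact for the piecewise-quadratic
# integrand of cubic-spline curvature products.
_GAUSS_X = np.array([0.5 - 0.5 / np.sqrt(3), 0.5 + 0.5 / np.sqrt(3)])
_GAUSS_W = np.array([0.5, 0.5])


class ModelError(ValueError):
    """Raised for unusable designs, mismatched fits or refused comparisons."""


# ---------------------------------------------------------------------------
# spline basis


def _knots(xmin: float, xmax: float, basis_dim: int) -> np.ndarray:
    if basis_dim < 4:
        raise ModelError("basis_dim must be >= 4 for a cubic basis")
    if xmax <= xmin:
        raise ModelError("predictor is constant; smooth is not identifiable")
    interior = np.linspace(xmin, xmax, basis_dim - 2)[1:-1]
    return np.concatenate([[xmin] * 4, interior, [xmax] * 4])


def _basis_matrix(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cubic B-spline design matrix; x is clamped to the knot range."""
    lo, hi = t[3], t[-4]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, t, 3).toarray()


def _curvature_penalty(t: np.ndarray) -> np.ndarray:
    """S_ij = integral of B_i''(x) B_j''(x) dx over the knot span."""
    nb = len(t) - 4
    splines = [BSpline(t, np.eye(nb)[i], 3).derivative(2) for i in range(nb)]
    breaks = np.unique(t)
    S = np.zeros((nb, nb))
    for a, b in zip(breaks[:-1], breaks[1:]):
        xg = a + (b - a) * _GAUSS_X
        wg = (b - a) * _GAUSS_W
        D = np.column_stack([s(xg) for s in splines])     # (2, nb)
        S += D.T @ (D * wg[:, None])
    return S


# ---------------------------------------------------------------------------
# penalized least squares core


@dataclass
class _Block:
    """One design block: columns plus its penalty matrix (None = ridge I).

    ``min_log_lam`` bounds the GCV search below: ridge blocks of group
    dummies are collinear with the intercept in the unpenalized limit, so
    their penalty keeps a small floor (a mixed model's ridge weight
    sigma^2/tau^2 is strictly positive).
    """

    name: str
    X: np.ndarray
    S: np.ndarray | None
    penalized: bool = True
    min_log_lam: float = -6.0


def _assemble(blocks: list[_Block]) -> tuple[np.ndarray, list[slice]]:
    cols = [np.ones((len(blocks[0].X), 1))]
    slices, start = [], 1
    for b in blocks:
        cols.append(b.X)
        slices.append(slice(start, start + b.X.shape[1]))
        start += b.X.shape[1]
    return np.hstack(cols), slices


def _penalty_matrix(blocks, slices, lam, p):
    P = np.zeros((p, p))
    for b, sl, lm in zip(blocks, slices, lam):
        if not b.penalized:
            continue
        S = b.S if b.S is not None else np.eye(sl.stop - sl.start)
        P[sl, sl] = lm * S
    return P


def _solve(XtX, Xty, P):
    A = XtX + P
    try:
        coef = np.linalg.solve(A, Xty)
        Ainv_XtX = np.linalg.solve(A, XtX)
    except np.linalg.LinAlgError:
        coef = np.linalg.lstsq(A, Xty, rcond=None)[0]
        Ainv_XtX = np.linalg.lstsq(A, XtX, rcond=None)[0]
    return coef, Ainv_XtX


def _fit_for_lambda(y, X, XtX, Xty, blocks, slices, log_lam):
    lam = 10.0 ** np.asarray(log_lam, dtype=float)
    P = _penalty_matrix(blocks, slices, lam, X.shape[1])
    coef, Ainv_XtX = _solve(XtX, Xty, P)
    fitted = X @ coef
    rss = float(np.sum((y - fitted) ** 2))
    edf = float(np.trace(Ainv_XtX))
    return coef, fitted, rss, edf, Ainv_XtX


def _gcv(y, X, XtX, Xty, blocks, slices, log_lam):
    n = len(y)
    _, _, rss, edf, _ = _fit_for_lambda(y, X, XtX, Xty, blocks, slices, log_lam)
    if not np.isfinite(edf) or edf < 0 or edf >= n:
        return np.inf        # numerically singular region
    denom = max(n - edf, 1e-8)
    return n * rss / denom ** 2


def _select_lambdas(y, X, XtX, Xty, blocks, slices) -> np.ndarray:
    """Joint GCV minimisation over log10 smoothing parameters."""
    npen = sum(1 for b in blocks if b.penalized)
    if npen == 0:
        return np.array([])

    def obj(log_lam):
        full = _expand(log_lam)
        return _gcv(y, X, XtX, Xty, blocks, slices, full)

    def _expand(log_lam):
        out, j = [], 0
        for b in blocks:
            if b.penalized:
                out.append(max(log_lam[j], b.min_log_lam))
                j += 1
            else:
                out.append(-np.inf)        # lambda = 0
        return out

    # coarse grid seed, then simplex refinement
    grid = np.arange(-4.0, 7.0, 1.0)
    best, best_val = np.zeros(npen), np.inf
    for g in grid:
        val = obj(np.full(npen, g))
        if val < best_val:
            best, best_val = np.full(npen, g), val
    res = optimize.minimize(obj, best, method="Nelder-Mead",
                            options={"maxiter": 200 * npen, "xatol": 1e-2,
                                     "fatol": 1e-10})
    chosen = res.x if res.fun <= best_val else best
    return np.asarray(_expand(chosen))


# ---------------------------------------------------------------------------
# public fit containers


@dataclass
class SmoothFit:
    """A fitted penalized-spline model.

    Carries everything needed to evaluate the fixed-effect curve on new
    data; random-effect intercepts are stored but evaluated at zero for
    prediction (population-level curve).
    """

    response_name: str
    predictor: str | tuple
    knots: dict                       # term -> knot vector
    col_means: dict                   # term -> basis column means
    coef: np.ndarray
    intercept: float
    term_slices: dict                 # term -> slice into coef
    random_effects: dict              # group name -> {level: intercept}
    lambdas: dict
    fitted_values: np.ndarray
    residuals: np.ndarray
    r2: float
    r2_adj: float
    deviance_explained: float
    aic: float
    edf: float
    edf_per_term: dict
    n_obs: int
    train_range: dict                 # term -> (min, max)
    data_fingerprint: int
    term_pvalues: dict = field(default_factory=dict)
    clamp_range: tuple | None = None

    def predict(self, newdata: pd.DataFrame | np.ndarray,
                clamp: bool | None = None) -> pd.DataFrame:
        """Population-level prediction; flags extrapolated rows.

        ``newdata`` is a frame holding the fit's predictor column(s) (or a
        bare array for a single-predictor fit).  Outside the training range
        the spline is evaluated at the range boundary (constant
        extrapolation) and the row is flagged.
        """
        terms = [self.predictor] if isinstance(self.predictor, str) \
            else list(self.predictor)
        if isinstance(newdata, (np.ndarray, list)):
            if len(terms) != 1:
                raise ModelError("array input only valid for one predictor")
            newdata = pd.DataFrame({terms[0]: np.asarray(newdata)})
        pred = np.full(len(newdata), self.intercept, dtype=float)
        extrapolated = np.zeros(len(newdata), dtype=bool)
        for term in terms:
            if term not in newdata.columns:
                raise ModelError(
                    f"fit was trained on predictor {term!r}; column missing")
            x = newdata[term].to_numpy(float)
            lo, hi = self.train_range[term]
            extrapolated |= (x < lo) | (x > hi)
            B = _basis_matrix(x, self.knots[term]) - self.col_means[term]
            pred += B @ self.coef[self.term_slices[term]]
        raw = pred.copy()
        if clamp is None:
            clamp = self.clamp_range is not None
        if clamp and self.clamp_range is not None:
            pred = np.clip(pred, *self.clamp_range)
        return pd.DataFrame({"predicted": pred, "predicted_unclamped": raw,
                             "extrapolated": extrapolated})


def _fingerprint(y: np.ndarray) -> int:
    return hash(tuple(np.round(np.asarray(y, float), 9)))


def _gaussian_aic(n: int, rss: float, edf: float) -> float:
    # conditional AIC on effective degrees of freedom (+1 for the scale)
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    return float(-2 * loglik + 2 * (edf + 1))


def _prepare_smooth_blocks(data, terms, basis_dim):
    blocks, knots, col_means, train_range = [], {}, {}, {}
    for term in terms:
        x = data[term].to_numpy(float)
        t = _knots(x.min(), x.max(), basis_dim)
        B = _basis_matrix(x, t)
        m = B.mean(axis=0)
        blocks.append(_Block(term, B - m, _curvature_penalty(t)))
        knots[term], col_means[term] = t, m
        train_range[term] = (float(x.min()), float(x.max()))
    return blocks, knots, col_means, train_range


def _fit_additive(data: pd.DataFrame, response: str, terms: list[str],
                  random_effects: tuple = (), basis_dim: int = DEFAULT_BASIS_DIM,
                  fixed_log_lambda: float | None = None,
                  clamp_range: tuple | None = None,
                  compute_pvalues: bool = False) -> SmoothFit:
    y = data[response].to_numpy(float)
    n = len(y)
    blocks, knots, col_means, train_range = _prepare_smooth_blocks(
        data, terms, basis_dim)
    if n < basis_dim + 2:
        raise ModelError(f"need at least basis_dim + 2 = {basis_dim + 2} "
                         f"observations, got {n}")

    re_levels: dict = {}
    re_terms = []
    for grp in random_effects:
        levels = pd.unique(data[grp])
        if len(levels) < 2:
            warnings.warn(f"random effect {grp!r} has a single level; dropped",
                          stacklevel=2)
            continue
        Z = (data[grp].to_numpy()[:, None] == levels[None, :]).astype(float)
        blocks.append(_Block(f"re_{grp}", Z, None, min_log_lam=-2.0))
        re_levels[grp] = list(levels)
        re_terms.append(grp)

    X, slices = _assemble(blocks)
    XtX, Xty = X.T @ X, X.T @ y

    if fixed_log_lambda is not None:
        log_lam = np.full(len(blocks), float(fixed_log_lambda))
    else:
        log_lam = _select_lambdas(y, X, XtX, Xty, blocks, slices)
    coef, fitted, rss, edf, Ainv_XtX = _fit_for_lambda(
        y, X, XtX, Xty, blocks, slices, log_lam)

    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    denom = max(n - edf - 1, 1e-8)
    r2_adj = 1.0 - (rss / denom) / (tss / max(n - 1, 1)) if tss > 0 else float("nan")

    edf_diag = np.diag(Ainv_XtX)
    term_slices, edf_per_term, lambdas = {}, {}, {}
    for b, sl, ll in zip(blocks, slices, log_lam):
        edf_per_term[b.name] = float(edf_diag[sl].sum())
        lambdas[b.name] = float(10.0 ** ll) if np.isfinite(ll) else 0.0
        if b.name in terms:
            term_slices[b.name] = sl

    res = {}
    for grp in re_terms:
        sl = slices[[b.name for b in blocks].index(f"re_{grp}")]
        res[grp] = dict(zip(re_levels[grp], coef[sl]))

    fit = SmoothFit(
        response_name=response,
        predictor=terms[0] if len(terms) == 1 else tuple(terms),
        knots=knots, col_means=col_means, coef=coef,
        intercept=float(coef[0]), term_slices=term_slices,
        random_effects=res, lambdas=lambdas,
        fitted_values=fitted, residuals=y - fitted,
        r2=r2, r2_adj=r2_adj,
        deviance_explained=r2,
        aic=_gaussian_aic(n, rss, edf), edf=edf,
        edf_per_term=edf_per_term, n_obs=n,
        train_range=train_range,
        data_fingerprint=_fingerprint(y),
        clamp_range=clamp_range,
    )

    if compute_pvalues:
        fit.term_pvalues = _term_pvalues(data, response, terms, blocks, slices,
                                         log_lam, y, rss, edf, n)
    return fit


def _term_pvalues(data, response, terms, blocks, slices, log_lam, y, rss_full,
                  edf_full, n) -> dict:
    """Approximate drop-term F-tests at the full model's smoothing levels."""
    pvals = {}
    scale = rss_full / max(n - edf_full, 1e-8)
    for term in terms:
        kept = [i for i, b in enumerate(blocks) if b.name != term]
        sub_blocks = [blocks[i] for i in kept]
        X, sub_slices = _assemble(sub_blocks)
        XtX, Xty = X.T @ X, X.T @ y
        sub_lam = [log_lam[i] for i in kept]
        _, _, rss_red, edf_red, _ = _fit_for_lambda(
            y, X, XtX, Xty, sub_blocks, sub_slices, sub_lam)
        df_num = max(edf_full - edf_red, 1e-8)
        F = max(rss_red - rss_full, 0.0) / df_num / max(scale, 1e-300)
        pvals[term] = float(stats.f.sf(F, df_num, max(n - edf_full, 1e-8)))
    return pvals


# ---------------------------------------------------------------------------
# spec-level operations


def screen_predictors(alignment: pd.DataFrame,
                      predictors: tuple = PREDICTORS,
                      flag_threshold: float = CORRELATION_FLAG) -> dict:
    """Pairwise Pearson correlations among candidate predictors.

    Pairs with |r| above ``flag_threshold`` are flagged for single-predictor
    modelling; constant predictors (undefined r) and degenerate two-point
    data (r forced to ±1) are reported as warnings.
    """
    if len(alignment) < 3:
        warnings.warn("fewer than 3 observations; correlations degenerate",
                      stacklevel=2)
    cols = [p for p in predictors if p in alignment.columns]
    mat = pd.DataFrame(np.nan, index=cols, columns=cols)
    flagged, warnings_out = [], []
    for i, a in enumerate(cols):
        mat.loc[a, a] = 1.0
        for b in cols[i + 1:]:
            xa = alignment[a].to_numpy(float)
            xb = alignment[b].to_numpy(float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                warnings_out.append(f"{a}~{b}: constant predictor, r undefined")
                continue
            r = float(stats.pearsonr(xa, xb)[0])
            mat.loc[a, b] = mat.loc[b, a] = r
            if len(xa) == 2:
                warnings_out.append(f"{a}~{b}: only 2 points, r degenerate")
            if abs(r) > flag_threshold:
                flagged.append((a, b, r))
    return {"correlation_matrix": mat, "flagged_pairs": flagged,
            "warnings": warnings_out}


def fit_phenophase_smooth(series: pd.DataFrame, predictor: str = "gdd",
                          random_effects: tuple = ("plot", "year"),
                          basis_dim: int = DEFAULT_BASIS_DIM,
                          fixed_log_lambda: float | None = None) -> SmoothFit:
    """Fit median phenophase ~ s(predictor) + (1|plot) + (1|year).

    ``series`` is an aligned plot-median table with columns
    ``median_phase``, the predictor, and the random-effect grouping columns.
    Predictions from the fit are clamped to the BBCH range [0, 59] (raw
    values retained alongside).
    """
    if predictor not in series.columns:
        raise ModelError(f"predictor {predictor!r} not in data")
    data = series.dropna(subset=["median_phase", predictor]).copy()
    if "year" in random_effects and "year" not in data.columns and "date" in data:
        data["year"] = pd.to_datetime(data["date"]).dt.year
    re_present = tuple(g for g in random_effects if g in data.columns)
    return _fit_additive(data, "median_phase", [predictor], re_present,
                         basis_dim=basis_dim, fixed_log_lambda=fixed_log_lambda,
                         clamp_range=(0.0, 59.0))


def compare_predictors(fits: dict[str, SmoothFit]) -> dict:
    """Rank single-predictor fits of the same response data by AIC.

    Refuses to compare fits whose response vectors differ (fingerprint
    check).  Ties (AIC difference below 1e-9) break by the documented
    predictor priority GDD > DFSM > DOY.
    """
    if not fits:
        raise ModelError("no fits to compare")
    prints = {f.data_fingerprint for f in fits.values()}
    if len(prints) > 1:
        raise ModelError("fits were trained on different response data")
    table = pd.DataFrame({
        "predictor": list(fits),
        "r2": [f.r2_adj for f in fits.values()],
        "aic": [f.aic for f in fits.values()],
        "edf": [f.edf for f in fits.values()],
    })
    priority = {p: i for i, p in enumerate(PREDICTORS)}
    table["_prio"] = table["predictor"].map(lambda p: priority.get(p, 99))
    table = table.sort_values(["aic", "_prio"]).reset_index(drop=True)
    best_aic = table["aic"].iloc[0]
    tied = table[np.abs(table["aic"] - best_aic) < 1e-9]
    winner = tied.sort_values("_prio")["predictor"].iloc[0]
    return {"table": table.drop(columns="_prio"), "winner": winner}


def fit_gcc_species_model(matched: pd.DataFrame, species: list[str],
                          basis_dim: int = 5) -> SmoothFit:
    """GCC ~ sum of per-species phenophase smooths.

    ``matched`` has one row per date with a ``gcc`` column and one
    phenophase column per species.  Requires at least 10 matched dates (the
    field design yields N = 17 site-season dates).  Reports adjusted R²,
    deviance explained, per-smooth edf and approximate drop-term p-values.
    """
    if len(matched) < 10:
        raise ModelError(
            f"need >= 10 matched dates, got {len(matched)}")
    missing = [s for s in species if s not in matched.columns]
    if missing:
        raise ModelError(f"phenophase columns missing: {missing}")
    n_coef = 1 + len(species)     # unpenalized dimensions: intercept + linears
    if len(matched) <= n_coef:
        raise ModelError(
            f"need more than {n_coef} dates for {len(species)} species smooths")
    return _fit_additive(matched.rename(columns={"gcc": "gcc_value"}),
                         "gcc_value", list(species), random_effects=(),
                         basis_dim=basis_dim, compute_pvalues=True)


def predict_cross_site(fit: SmoothFit, early_alignment: pd.DataFrame,
                       predictor: str | None = None) -> pd.DataFrame:
    """Space-for-time transfer: apply a late-site fit to early-site covariates.

    ``early_alignment`` must carry the fit's predictor column; the returned
    frame holds clamped predictions with extrapolation flags.  An empty
    table yields an empty prediction.
    """
    predictor = predictor or fit.predictor
    if predictor != fit.predictor:
        raise ModelError(
            f"fit was trained on {fit.predictor!r}, not {predictor!r}")
    if len(early_alignment) == 0:
        return pd.DataFrame(columns=["predicted", "predicted_unclamped",
                                     "extrapolated"])
    if isinstance(fit.predictor, str) and \
            fit.predictor not in early_alignment.columns:
        raise ModelError(f"column {fit.predictor!r} missing from target table")
    out = fit.predict(early_alignment)
    n_extra = int(out["extrapolated"].sum())
    if n_extra:
        logger.info("%d prediction(s) beyond the training range", n_extra)
    return out


def assess_predictions(predicted, observed, stage_width: float = 10.0) -> dict:
    """Pearson r, mean absolute error (BBCH units) and per-stage residuals."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ModelError("predicted and observed lengths differ")
    if p.size == 0:
        raise ModelError("empty prediction set")
    resid = p - o
    if np.std(p) == 0 or np.std(o) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(p, o)[0])
    bins = (np.floor(o / stage_width) * stage_width).astype(int)
    per_stage = (pd.DataFrame({"stage_bin": bins, "residual": resid})
                 .groupby("stage_bin")["residual"]
                 .agg(["mean", "std", "count"]))
    return {
        "pearson_r": r,
        "mean_abs_error_phases": float(np.mean(np.abs(resid))),
        "residuals": resid,
        "per_stage": per_stage,
    }
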