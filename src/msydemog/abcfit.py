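"""Approximate Bayesian computation on derived-SFS summaries.

The pipeline mirrors the classical rejection / regression ABC toolchain:

* summaries are the derived SFS restricted to categories with at least one
  observed polymorphic site, each retained category scaled by its median
  absolute deviation (MAD) across the reference table;
* rejection keeps the ``n_accept`` simulations nearest in Euclidean
  distance;
* model choice is multinomial logistic regression of the model label on the
  scaled summaries, fitted on the nearest rows and evaluated at the
  observed summary (ridge-stabilised against separation), with plain
  rejection counting available as a cross-check;
* parameter estimation is local-linear regression adjustment
  (Epanechnikov-weighted least squares) of each parameter after a *logtan*
  transformation, which maps a bounded parameter onto the real line so the
  back-transformed posterior always respects the prior support; the
  per-parameter R^2 reports how much parameter variance the summaries
  explain.

Two scikit-learn style estimators, :class:`ABCModelChoice` and
:class:`ABCPosterior`, wrap the functional core for pipeline use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .coalescent import simulate_batch
from .demography import ModelSpec, UniformPrior

__all__ = [
    "sfs_columns",
    "SummaryScaler",
    "build_summary",
    "RejectionResult",
    "reject",
    "model_posterior_rejection",
    "model_choice_logistic",
    "logtan",
    "logtan_inverse",
    "PosteriorSummary",
    "local_linear_adjust",
    "power_analysis",
    "parameter_recovery_suite",
    "ABCModelChoice",
    "ABCPosterior",
]


def sfs_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("xi_")]


@dataclass(frozen=True)
class SummaryScaler:
    """Category mask plus per-category MAD scale, shared by observed and sims."""

    mask: np.ndarray  # indices of retained SFS categories (0-based)
    scale: np.ndarray  # MAD per retained category (zero MAD -> 1)

    def transform(self, sfs: np.ndarray) -> np.ndarray:
        sfs = np.atleast_2d(np.asarray(sfs, dtype=float))
        return sfs[:, self.mask] / self.scale


def build_summary(
    observed_sfs: np.ndarray, table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, SummaryScaler]:
    """Mask and scale summaries.

    The mask keeps the SFS categories with at least one observed
    polymorphic site; each retained category is scaled by its MAD across
    the reference table (1 where the MAD is zero).  Returns the scaled
    observed vector, the scaled simulation matrix and the scaler.
    """
    obs = np.asarray(observed_sfs, dtype=float).ravel()
    if obs.sum() <= 0:
        raise ValueError("observed SFS has no polymorphic sites")
    sims = table[sfs_columns(table)].to_numpy(dtype=float)
    if sims.shape[1] != len(obs):
        raise ValueError(
            f"observed SFS has {len(obs)} categories, table has {sims.shape[1]}"
        )
    mask = np.where(obs >= 1)[0]
    mad = sps.median_abs_deviation(sims[:, mask], axis=0)
    scale = np.where(mad > 0, mad, 1.0)
    scaler = SummaryScaler(mask=mask, scale=scale)
    return scaler.transform(obs)[0], scaler.transform(sims), scaler


@dataclass(frozen=True)
class RejectionResult:
    indices: np.ndarray  # row indices into the table, nearest first
    distances: np.ndarray  # matching Euclidean distances
    tolerance: float  # largest accepted distance


def reject(
    observed: np.ndarray,
    summaries: np.ndarray,
    n_accept: int,
    rng: np.random.Generator | int | None = 0,
) -> RejectionResult:
    """Keep the ``n_accept`` simulations nearest to the observed summary.

    Distances are Euclidean on the scaled summaries.  Boundary ties are
    broken by row order after a seeded shuffle, so the result is
    deterministic given the seed yet unbiased with respect to table order.
    """
    if n_accept <= 0:
        raise ValueError("n_accept must be positive")
    n_rows = summaries.shape[0]
    if n_accept > n_rows:
        raise ValueError("n_accept exceeds table size")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d = np.sqrt(((summaries - observed) ** 2).sum(axis=1))
    perm = rng.permutation(n_rows)
    order = perm[np.argsort(d[perm], kind="stable")]
    acc = order[:n_accept]
    return RejectionResult(indices=acc, distances=d[acc], tolerance=float(d[acc].max()))


def model_posterior_rejection(models: pd.Series | np.ndarray) -> pd.Series:
    """Model posterior as the per-model share of accepted rows."""
    models = pd.Series(models)
    if models.empty:
        raise ValueError("no accepted rows")
    return models.value_counts(normalize=True).sort_index()


def model_choice_logistic(
    observed: np.ndarray,
    summaries: np.ndarray,
    models: np.ndarray,
    n_keep: int,
    rng: np.random.Generator | int | None = 0,
    C: float = 1.0,
) -> pd.Series:
    """Posterior model probabilities by multinomial logistic regression.

    Fitted on the ``n_keep`` rows nearest to the observed summary and
    evaluated at the observed summary.  L2 (ridge) regularisation keeps the
    fit defined under perfect separation.  A model absent from the kept
    rows gets probability 0 with a warning.
    """
    models = np.asarray(models)
    all_models = np.unique(models)
    if len(all_models) < 2:
        raise ValueError("model choice requires >= 2 models")
    res = reject(observed, summaries, n_keep, rng)
    kept_y = models[res.indices]
    kept_X = summaries[res.indices]
    present = np.unique(kept_y)
    missing = sorted(set(all_models) - set(present))
    if missing:
        warnings.warn(f"models absent from kept rows get probability 0: {missing}")
    if len(present) < 2:
        probs = pd.Series(0.0, index=all_models)
        probs[present[0]] = 1.0
        return probs
    clf = LogisticRegression(C=C, max_iter=2000)  # default L2 ridge
    clf.fit(kept_X, kept_y)
    p = clf.predict_proba(observed.reshape(1, -1))[0]
    probs = pd.Series(0.0, index=all_models)
    probs[clf.classes_] = p
    return probs / probs.sum()


_EPS = 1e-12


def logtan(x, prior: UniformPrior):
    """Map x in (lower, upper) onto the real line: y = ln(tan(u * pi/2)).

    Values at or outside the bounds are clamped just inside (relative
    machine epsilon) with a warning rather than returning infinities.
    """
    x = np.asarray(x, dtype=float)
    u = (x - prior.lower) / prior.width
    if np.any(u <= 0) or np.any(u >= 1):
        warnings.warn("logtan input at/outside prior bounds; clamping inside")
        u = np.clip(u, _EPS, 1 - _EPS)
    out = np.log(np.tan(u * math.pi / 2.0))
    return float(out) if out.ndim == 0 else out


def logtan_inverse(y, prior: UniformPrior):
    """Inverse of :func:`logtan`: any real maps back into (lower, upper).

    Extreme inputs that would saturate to a bound in floating point are
    kept strictly inside the open support.
    """
    y = np.asarray(y, dtype=float)
    with np.errstate(over="ignore"):
        u = 2.0 / math.pi * np.arctan(np.exp(y))
    u = np.clip(u, _EPS, 1 - _EPS)
    out = prior.lower + u * prior.width
    return float(out) if out.ndim == 0 else out


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cw = (cw - 0.5 * w) / cw[-1]
    return np.interp(np.atleast_1d(q), cw, x)


@dataclass
class PosteriorSummary:
    """Adjusted posterior for one parameter."""

    name: str
    sample: np.ndarray  # back-transformed adjusted draws
    weights: np.ndarray
    median: float
    mode: float
    ci_low: float
    ci_high: float
    r2: float
    adjusted: bool  # False when the regression fell back to rejection


def _kde_mode(x: np.ndarray, w: np.ndarray) -> float:
    if np.ptp(x) < 1e-12:
        return float(np.median(x))
    try:
        kde = sps.gaussian_kde(x, weights=w)
    except np.linalg.LinAlgError:
        return float(_weighted_quantile(x, w, 0.5)[0])
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _summarize(name, sample, weights, r2, adjusted) -> PosteriorSummary:
    lo, med, hi = _weighted_quantile(sample, weights, [0.025, 0.5, 0.975])
    return PosteriorSummary(
        name=name,
        sample=sample,
        weights=weights,
        median=float(med),
        mode=_kde_mode(sample, weights),
        ci_low=float(lo),
        ci_high=float(hi),
        r2=r2,
        adjusted=adjusted,
    )


def local_linear_adjust(
    accepted_params: pd.DataFrame,
    accepted_summaries: np.ndarray,
    distances: np.ndarray,
    tolerance: float,
    observed: np.ndarray,
    priors: dict[str, UniformPrior],
    derive_t1: bool = True,
) -> dict[str, PosteriorSummary]:
    """Regression-adjusted posteriors for each parameter with a prior.

    Each parameter is logtan-transformed, regressed on the scaled summaries
    by Epanechnikov-weighted least squares, shifted to its fit at the
    observed summary plus residuals, and back-transformed.  The derived
    time T1 = T2 + LEX is recomposed from the adjusted T2 and LEX samples
    rather than regressed directly.  On a singular design the parameter
    falls back to its unadjusted (rejection) posterior, flagged with
    ``adjusted=False``.
    """
    n_acc = len(accepted_params)
    if accepted_summaries.shape[0] != n_acc:
        raise ValueError("params/summaries row mismatch")
    if tolerance > 0:
        w = 1.0 - (distances / tolerance) ** 2
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            w = np.ones(n_acc)
    else:
        w = np.ones(n_acc)
    X = np.column_stack([np.ones(n_acc), accepted_summaries - observed])
    sw = np.sqrt(w)
    out: dict[str, PosteriorSummary] = {}
    for name, prior in priors.items():
        y = logtan(accepted_params[name].to_numpy(dtype=float), prior)
        beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if rank < X.shape[1]:
            sample = logtan_inverse(y, prior)
            out[name] = _summarize(name, sample, w, math.nan, adjusted=False)
            continue
        resid = y - X @ beta
        y_adj = beta[0] + resid
        ybar = np.average(y, weights=w)
        ss_tot = float(np.sum(w * (y - ybar) ** 2))
        ss_res = float(np.sum(w * resid**2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
        sample = logtan_inverse(y_adj, prior)
        out[name] = _summarize(name, sample, w, r2, adjusted=True)
    if derive_t1 and "T2" in out and "LEX" in out:
        t1 = out["T2"].sample + out["LEX"].sample
        out["T1"] = _summarize(
            "T1", t1, w, math.nan, adjusted=out["T2"].adjusted and out["LEX"].adjusted
        )
    return out


def power_analysis(
    specs: list[ModelSpec],
    table: pd.DataFrame,
    n_pods: int,
    n_keep: int,
    n: int,
    seed: int,
    method: str = "logistic",
) -> pd.DataFrame:
    """Confusion matrix of ABC model choice over pseudo-observed datasets.

    For each model, ``n_pods`` datasets are simulated from its prior; the
    fitted model is the argmax posterior model.  Rows are generating
    models, columns chosen models; the diagonal holds true-positive rates
    and each row sums to 1.
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    model_ids = [s.model_id for s in specs]
    if len(set(model_ids)) < 2:
        raise ValueError("power analysis requires >= 2 distinct models")
    models = table["model"].to_numpy()
    sims_raw = table[sfs_columns(table)].to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed)
    conf = pd.DataFrame(0.0, index=model_ids, columns=model_ids)
    for spec, child in zip(specs, ss.spawn(len(specs))):
        pods = simulate_batch(spec, n_pods, n, child)
        pod_sfs = pods[sfs_columns(pods)].to_numpy(dtype=float)
        pick_rng = np.random.default_rng(child.spawn(1)[0])
        for row in pod_sfs:
            if row.sum() <= 0:
                continue  # degenerate pod: no polymorphism, no summary
            obs, sims, _ = build_summary(row, table)
            if method == "logistic":
                probs = model_choice_logistic(obs, sims, models, n_keep, pick_rng)
            else:
                res = reject(obs, sims, n_keep, pick_rng)
                probs = model_posterior_rejection(models[res.indices])
            conf.loc[spec.model_id, probs.idxmax()] += 1
        conf.loc[spec.model_id] /= conf.loc[spec.model_id].sum()
    return conf


def parameter_recovery_suite(
    spec: ModelSpec,
    table: pd.DataFrame,
    n_pods: int,
    n_accept: int,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Coverage of the 95% credible intervals over pseudo-observed datasets.

    Each pod draws true parameters from the prior, simulates a dataset,
    runs rejection plus regression adjustment against the reference table
    (which never contains the pod itself), and records whether each
    parameter's interval covers the generating value.
    """
    from .demography import build_demography, sample_prior
    from .coalescent import coalescent_sim, compute_derived_sfs, drop_mutations

    ss = np.random.SeedSequence(seed)
    params_cols = list(spec.parameter_names)
    covered = {p: 0 for p in params_cols}
    used = 0
    for child in ss.spawn(n_pods):
        rng = np.random.default_rng(child)
        truth = sample_prior(spec, rng)
        g = coalescent_sim(build_demography(truth), n, rng)
        sfs = compute_derived_sfs(drop_mutations(g, truth.mu, spec.locus_length_bp, rng))
        if sfs.total == 0:
            continue
        obs, sims, _ = build_summary(sfs.counts, table)
        res = reject(obs, sims, n_accept, rng)
        post = local_linear_adjust(
            table.iloc[res.indices][params_cols],
            sims[res.indices],
            res.distances,
            res.tolerance,
            obs,
            {p: spec.priors[p] for p in params_cols},
            derive_t1=False,
        )
        used += 1
        for p in params_cols:
            if post[p].ci_low <= truth.values[p] <= post[p].ci_high:
                covered[p] += 1
    if used == 0:
        raise RuntimeError("no usable pods (all devoid of polymorphism)")
    return pd.DataFrame(
        {"parameter": params_cols, "coverage": [covered[p] / used for p in params_cols],
         "n_pods": used}
    )


class ABCModelChoice(BaseEstimator):
    """scikit-learn style ABC model-choice classifier.

    ``fit`` memorises the reference summaries (raw SFS rows) and their
    model labels; ``predict_proba`` masks and scales per observed SFS,
    then runs logistic (default) or rejection model choice.

    Parameters
    ----------
    n_keep : int or float
        Rows retained for the fit; a float in (0, 1) is a fraction of the
        table (default 0.01, the 10,000-in-1,000,000 convention).
    method : {"logistic", "rejection"}
    C : float
        Inverse ridge strength for the logistic fit.
    random_state : int
        Seed for tie-breaking shuffles.
    """

    def __init__(self, n_keep=0.01, method="logistic", C=1.0, random_state=0):
        self.n_keep = n_keep
        self.method = method
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if len(np.unique(y)) < 2:
            raise ValueError("need >= 2 models")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def _n_keep(self) -> int:
        if 0 < self.n_keep < 1:
            return max(2, int(round(self.n_keep * len(self.X_))))
        return int(self.n_keep)

    def predict_proba(self, X) -> pd.DataFrame:
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        table = pd.DataFrame(self.X_, columns=[f"xi_{i+1}" for i in range(self.X_.shape[1])])
        out = []
        for row in X:
            obs, sims, _ = build_summary(row, table)
            if self.method == "logistic":
                probs = model_choice_logistic(
                    obs, sims, self.y_, self._n_keep(), self.random_state, C=self.C
                )
            elif self.method == "rejection":
                res = reject(obs, sims, self._n_keep(), self.random_state)
                probs = model_posterior_rejection(self.y_[res.indices]).reindex(
                    self.classes_, fill_value=0.0
                )
            else:
                raise ValueError(f"unknown method {self.method!r}")
            out.append(probs.reindex(self.classes_, fill_value=0.0))
        return pd.DataFrame(out).reset_index(drop=True)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).idxmax(axis=1).to_numpy()


class ABCPosterior(BaseEstimator):
    """scikit-learn style rejection + regression-adjustment estimator.

    ``fit`` memorises the single-model reference table; ``posterior``
    returns the adjusted :class:`PosteriorSummary` per parameter for one
    observed SFS.
    """

    def __init__(self, priors=None, n_accept=0.01, random_state=0):
        self.priors = priors
        self.n_accept = n_accept
        self.random_state = random_state

    def fit(self, X, y):
        """X: (n_sims, n_categories) raw SFS rows; y: parameter DataFrame."""
        X = np.asarray(X, dtype=float)
        y = pd.DataFrame(y)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if not self.priors:
            raise ValueError("priors are required")
        missing = set(self.priors) - set(y.columns)
        if missing:
            raise ValueError(f"parameters missing from y: {sorted(missing)}")
        self.X_ = X
        self.params_ = y.reset_index(drop=True)
        return self

    def _n_accept(self) -> int:
        if 0 < self.n_accept < 1:
            return max(2, int(round(self.n_accept * len(self.X_))))
        return int(self.n_accept)

    def posterior(self, observed_sfs) -> dict[str, PosteriorSummary]:
        check_is_fitted(self, "X_")
        table = pd.DataFrame(self.X_, columns=[f"xi_{i+1}" for i in range(self.X_.shape[1])])
        obs, sims, _ = build_summary(np.asarray(observed_sfs, dtype=float), table)
        res = reject(obs, sims, self._n_accept(), self.random_state)
        return local_linear_adjust(
            self.params_.iloc[res.indices],
            sims[res.indices],
            res.distances,
            res.tolerance,
            obs,
            self.priors,
        )
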