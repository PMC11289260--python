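"""Factor-analysis latent state of population spike counts.

The population model is Gaussian factor analysis,

    x ~ N(mu, L L^T + Psi),

with loading matrix ``L`` (units x m) capturing the shared covariance
and diagonal ``Psi`` the private (independent) spike-count variance.
Parameters are estimated by expectation-maximisation on the sample
covariance; the log-likelihood is non-decreasing across iterations and
is exposed per iteration.  Dimensionality is chosen by 3-fold
cross-validated likelihood over a grid of ``m``, and ``m_opt`` is the
smallest number of eigendimensions of ``L L^T`` explaining 95% of the
shared variance.

Counts are preprocessed as: drop units with mean smoothed rate < 1 Hz,
square-root transform, Gaussian smooth (SD 35 ms), z-score per unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .binning import BIN_MS
from .smoothing import DEFAULT_SMOOTH_SD_MS, gaussian_smooth

logger = logging.getLogger(__name__)

_PSI_FLOOR = 1e-8


@dataclass
class FAModel:
    """Fitted factor-analysis model."""

    mu: np.ndarray  # (p,)
    loading: np.ndarray  # (p, m)
    psi: np.ndarray  # (p,)
    m: int
    loglik_path: np.ndarray
    converged: bool
    cv_loglik: dict | None = None  # m -> held-out loglik (when selected)
    m_opt: int | None = None

    @property
    def shared_cov(self) -> np.ndarray:
        return self.loading @ self.loading.T

    def posterior_mean(self, X: np.ndarray) -> np.ndarray:
        """E[z | x] for rows of ``X``; returns (n, m)."""
        C = self.shared_cov + np.diag(self.psi)
        beta = np.linalg.solve(C, self.loading).T  # (m, p)
        return (np.asarray(X) - self.mu) @ beta.T


@dataclass
class PreprocessResult:
    data: np.ndarray  # (n_trials, n_kept, n_bins), transformed
    kept_units: np.ndarray  # indices into the input unit axis
    mean_rate_hz: np.ndarray  # per input unit

    @property
    def samples(self) -> np.ndarray:
        """(n_trials * n_bins, n_kept) sample matrix (time within trial fast)."""
        d = np.moveaxis(self.data, 1, 2)  # trials, bins, units
        return d.reshape(-1, d.shape[-1])

    @property
    def sample_trials(self) -> np.ndarray:
        """Trial index of every row of :attr:`samples`."""
        n_trials, _, n_bins = self.data.shape
        return np.repeat(np.arange(n_trials), n_bins)


def preprocess(
    counts: np.ndarray,
    rate_threshold_hz: float = 1.0,
    smooth_sd_ms: float = DEFAULT_SMOOTH_SD_MS,
    smooth: bool = True,
    zscore: bool = True,
    bin_ms: float = BIN_MS,
) -> PreprocessResult:
    """Rate-filter, sqrt-transform, smooth and z-score binned counts.

    ``counts`` is (n_trials, n_units, n_bins).  Units whose mean smoothed
    rate falls below 1 Hz are excluded, as are zero-variance units (with
    a log entry), so downstream z-scores are always finite.
    """
    counts = np.asarray(counts, dtype=float)
    hz = 1000.0 / bin_ms
    rate = counts.mean(axis=(0, 2)) * hz
    keep = rate >= rate_threshold_hz
    if not np.any(keep):
        raise ValueError("all units fall below the firing-rate threshold")
    X = np.sqrt(counts[:, keep, :])
    if smooth:
        X = gaussian_smooth(X, sd_ms=smooth_sd_ms, bin_ms=bin_ms, axis=-1)
    if zscore:
        mu = X.mean(axis=(0, 2), keepdims=True)
        sd = X.std(axis=(0, 2), keepdims=True)
        nonzero = sd[0, :, 0] > 0
        if not np.all(nonzero):
            dropped = np.flatnonzero(keep)[~nonzero]
            logger.info("dropping %d zero-variance units: %s",
                        len(dropped), dropped.tolist())
            X = X[:, nonzero, :]
            mu, sd = mu[:, nonzero], sd[:, nonzero]
            keep_idx = np.flatnonzero(keep)[nonzero]
        else:
            keep_idx = np.flatnonzero(keep)
        X = (X - mu) / sd
    else:
        keep_idx = np.flatnonzero(keep)
    return PreprocessResult(data=X, kept_units=keep_idx, mean_rate_hz=rate)


def _gauss_loglik(S: np.ndarray, C: np.ndarray, n: int) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    return float(-0.5 * n * (p * np.log(2 * np.pi) + logdet
                             + np.trace(np.linalg.solve(C, S))))


def fit_fa(
    X: np.ndarray,
    m: int,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> FAModel:
    """Fit an m-factor model by EM (PCA initialisation, deterministic).

    Convergence when the relative log-likelihood improvement drops below
    ``tol``; a non-converged fit is returned with ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    n, p = X.shape
    if m >= p:
        raise ValueError("m must be < number of units")
    mu = X.mean(axis=0)
    Xc = X - mu
    S = (Xc.T @ Xc) / n

    evals, evecs = np.linalg.eigh(S)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    resid = max(evals[m:].mean(), _PSI_FLOOR) if m < p else _PSI_FLOOR
    L = evecs[:, :m] * np.sqrt(np.clip(evals[:m] - resid, _PSI_FLOOR, None))
    psi = np.clip(np.diag(S) - np.sum(L**2, axis=1), _PSI_FLOOR, None)

    path = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        C = L @ L.T + np.diag(psi)
        ll = _gauss_loglik(S, C, n)
        path.append(ll)
        if np.isfinite(prev) and ll - prev < tol * abs(prev):
            converged = True
            break
        prev = ll
        beta = np.linalg.solve(C, L).T  # (m, p)
        Ezz = np.eye(m) - beta @ L + beta @ S @ beta.T
        L = S @ beta.T @ np.linalg.inv(Ezz)
        psi = np.clip(np.diag(S) - np.diag(L @ beta @ S), _PSI_FLOOR, None)
    return FAModel(mu=mu, loading=L, psi=psi, m=m,
                   loglik_path=np.array(path), converged=converged)


def heldout_loglik(model: FAModel, X: np.ndarray) -> float:
    """Gaussian log-likelihood of held-out rows under a fitted model."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Xc = X - model.mu
    S = (Xc.T @ Xc) / n
    C = model.shared_cov + np.diag(model.psi)
    return _gauss_loglik(S, C, n)


def shared_dimensionality(model: FAModel, frac: float = 0.95) -> int:
    """Smallest k whose top-k eigenvalues of LL^T reach ``frac`` of its trace."""
    ev = np.linalg.eigvalsh(model.shared_cov)[::-1]
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total == 0:
        return 0
    cum = np.cumsum(ev) / total
    return int(np.searchsorted(cum, frac - 1e-12) + 1)


def select_dimensionality(
    X: np.ndarray,
    m_grid,
    n_folds: int = 3,
    rng: np.random.Generator | int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    groups: np.ndarray | None = None,
) -> FAModel:
    """Cross-validated choice of m, final fit, and m_opt.

    Rows are split into ``n_folds`` folds; for each candidate m the
    summed held-out log-likelihood is computed, m* maximises it, and the
    returned model is fit on all rows with ``m = m*``.  ``m_opt`` (95%
    shared-variance dimensionality) and the CV curve are attached.

    When ``groups`` is given (e.g. the trial index of each row), whole
    groups are assigned to folds.  Temporally smoothed samples from the
    same trial are strongly dependent, so splitting them across folds
    leaks training information into the held-out likelihood and inflates
    the selected dimensionality.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    m_grid = list(m_grid)
    if not m_grid:
        raise ValueError("empty m grid")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if groups is None:
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
    else:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        uniq = uniq[rng.permutation(len(uniq))]
        gfolds = np.array_split(uniq, n_folds)
        folds = [np.flatnonzero(np.isin(groups, gf)) for gf in gfolds]
    cv: dict = {}
    for m in m_grid:
        total = 0.0
        for k in range(n_folds):
            test = folds[k]
            train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            model = fit_fa(X[train], m, tol=tol, max_iter=max_iter)
            total += heldout_loglik(model, X[test])
        cv[m] = total
    if not np.isfinite(max(cv.values())):
        raise ValueError("degenerate held-out likelihoods across the m grid")
    m_star = max(cv, key=cv.get)
    final = fit_fa(X, m_star, tol=tol, max_iter=max_iter * 10)
    final.cv_loglik = cv
    final.m_opt = shared_dimensionality(final)
    return final


@dataclass
class SharedVarianceMetrics:
    percent_shared: np.ndarray  # per unit
    mean_percent_shared: float
    loading_similarity: float
    m_opt: int


def shared_variance_metrics(model: FAModel) -> SharedVarianceMetrics:
    """% shared variance per unit, loading similarity of factor 1, m_opt.

    %SV_i = s_i / (s_i + psi_i) * 100 with s_i the i-th diagonal entry
    of LL^T.  Loading similarity of the unit-normalised first-factor
    weight vector u is 1 - var(u)/(1/n) (sample variance, divisor n-1),
    so equal weights give exactly 1 and a one-hot vector exactly 0;
    values are clipped to [0, 1].
    """
    s = np.diag(model.shared_cov)
    denom = s + model.psi
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, s / denom * 100.0, np.nan)
    u = model.loading[:, 0]
    norm = np.linalg.norm(u)
    n = len(u)
    if norm == 0:
        ls = np.nan
    else:
        u = u / norm
        ls = float(np.clip(1.0 - np.var(u, ddof=1) / (1.0 / n), 0.0, 1.0))
    m_opt = model.m_opt if model.m_opt is not None else shared_dimensionality(model)
    return SharedVarianceMetrics(
        percent_shared=pct,
        mean_percent_shared=float(np.nanmean(pct)),
        loading_similarity=ls,
        m_opt=m_opt,
    )


def latent_trajectories(
    model: FAModel,
    pre: PreprocessResult,
    conditions: np.ndarray,
) -> dict:
    """Posterior-mean latent trajectories, single-trial and trial-averaged.

    ``conditions`` assigns a hashable condition label to every trial of
    ``pre.data``.  Returns ``{"single": (n_trials, m, T) array,
    "mean": {condition: (m, T)}}``.
    """
    data = pre.data  # trials, units, bins
    n_trials, p, T = data.shape
    flat = np.moveaxis(data, 1, 2).reshape(-1, p)
    Z = model.posterior_mean(flat).reshape(n_trials, T, model.m)
    Z = np.moveaxis(Z, 1, 2)  # trials, m, T
    conditions = np.asarray(conditions)
    mean = {c: Z[conditions == c].mean(axis=0) for c in np.unique(conditions)}
    return {"single": Z, "mean": mean}


def sliding_shared_variance(
    counts: np.ndarray,
    m: int,
    window_bins: int = 20,
    step_bins: int = 10,
    rate_threshold_hz: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 300,
):
    """Shared-variance metrics over time from per-window FA refits.

    ``counts`` is (n_trials, n_units, n_bins).  For each sliding window
    an FA model with ``m`` factors is fit to the *unsmoothed* per-window
    samples (sqrt-transformed and z-scored); smoothing is deliberately
    omitted here because within a 200 ms window it would leave too few
    independent samples per trial.  Returns a list of
    ``(window_start_bin, SharedVarianceMetrics)`` pairs.
    """
    from .binning import window_starts

    counts = np.asarray(counts, dtype=float)
    starts = window_starts(counts.shape[2], window_bins, step_bins)
    out = []
    for s in starts:
        pre = preprocess(counts[:, :, s : s + window_bins],
                         rate_threshold_hz=rate_threshold_hz, smooth=False)
        model = fit_fa(pre.samples, m, tol=tol, max_iter=max_iter)
        out.append((int(s), shared_variance_metrics(model)))
    return out
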