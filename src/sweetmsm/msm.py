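"""Markov-state-model construction and validation.

Implements the six-step construction/validation protocol used for
adaptive-sampling MD datasets: tICA featurization, k-means microstate
discretization, reversible maximum-likelihood transition-matrix estimation,
implied-timescale convergence, VAMP-2 scored hyperparameter grid search,
raw-versus-reweighted count validation, and the Chapman--Kolmogorov test.

All estimators here are authored from scratch on numpy/scipy; scikit-learn
is used only for the k-means steps.  The stationary distribution of the
reversible MSM supplies per-frame weights (pi_i / N_i) that remove the
seeding bias introduced by adaptive sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.stats
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .errors import EstimationError, InvalidParameterError

# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_traj_list(data) -> list[np.ndarray]:
    if isinstance(data, np.ndarray):
        return [data]
    if hasattr(data, "values") and hasattr(data, "names"):  # FeatureMatrix
        return [np.asarray(data.values, dtype=float)]
    return [np.asarray(d.values if hasattr(d, "values") else d) for d in data]


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------


@dataclass
class TICAModel:
    """Time-lagged independent component analysis model.

    Solves the symmetrized generalized eigenproblem ``C(tau) v = lambda
    C(0) v`` on mean-free data; components are ordered by descending
    eigenvalue and normalized to unit variance under the instantaneous
    covariance metric (``v^T C(0) v = 1``)."""

    lag: int
    eigenvalues: np.ndarray  # (k,) descending
    components: np.ndarray  # (n_features, k)
    mean: np.ndarray  # (n_features,)
    regularization: float

    def transform(self, data):
        trajs = _as_traj_list(data)
        out = [(t - self.mean) @ self.components for t in trajs]
        return out[0] if isinstance(data, np.ndarray) or hasattr(data, "names") else out


def _tica_covariances(trajs: list[np.ndarray], lag: int):
    d = trajs[0].shape[1]
    s0 = np.zeros(d)
    n = 0
    for t in trajs:
        if t.shape[0] >= lag + 2:
            s0 += t[:-lag].sum(axis=0) + t[lag:].sum(axis=0)
            n += 2 * (t.shape[0] - lag)
    if n == 0:
        raise InvalidParameterError("no trajectory long enough for the tICA lag")
    mean = s0 / n
    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    for t in trajs:
        if t.shape[0] < lag + 2:
            continue
        x = t[:-lag] - mean
        y = t[lag:] - mean
        c0 += x.T @ x + y.T @ y
        ct += x.T @ y
    c0 /= n
    ct = (ct + ct.T) / n  # symmetrized time-lagged covariance
    return mean, c0, ct


def tica_fit(features, lag: int, n_components: int | None = None,
             regularization: float = 1e-10) -> TICAModel:
    """Fit tICA on one or several feature trajectories."""
    if lag < 1:
        raise InvalidParameterError("tICA lag must be >= 1")
    trajs = _as_traj_list(features)
    mean, c0, ct = _tica_covariances(trajs, lag)
    d = c0.shape[0]
    c0reg = c0 + regularization * np.eye(d)
    try:
        evals, evecs = scipy.linalg.eigh(ct, c0reg)
    except scipy.linalg.LinAlgError as exc:
        raise EstimationError(
            "singular instantaneous covariance; increase the regularization "
            "parameter epsilon"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if n_components is not None:
        evals, evecs = evals[:n_components], evecs[:, :n_components]
    return TICAModel(lag=int(lag), eigenvalues=evals, components=evecs,
                     mean=mean, regularization=float(regularization))


def feature_tic_correlations(model: TICAModel, features, names=None) -> pd.DataFrame:
    """Pearson correlation of every input feature with every tIC projection.

    Constant features are reported with correlation 0 and ``constant=True``.
    """
    trajs = _as_traj_list(features)
    if names is None and hasattr(features, "names"):
        names = list(features.names)
    X = np.vstack(trajs)
    Y = (X - model.mean) @ model.components
    n_feat, n_tic = X.shape[1], Y.shape[1]
    if names is None:
        names = [f"f{i}" for i in range(n_feat)]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = Yc.std(axis=0)
    const = sx == 0
    corr = np.zeros((n_feat, n_tic))
    ok = ~const
    sy_safe = np.where(sy == 0, 1.0, sy)
    if np.any(ok):
        corr[ok] = (Xc[:, ok].T @ Yc) / X.shape[0] / np.outer(sx[ok], sy_safe)
        corr[:, sy == 0] = 0.0
    table = pd.DataFrame(corr, index=names,
                         columns=[f"tIC{k + 1}" for k in range(n_tic)])
    table["constant"] = const
    return table


# ---------------------------------------------------------------------------
# microstate clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    centers: np.ndarray

    def assign(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.centers[None]) ** 2).sum(axis=-1)
        return np.argmin(d2, axis=1)


def cluster_microstates(projections, k: int, seed: int = 0):
    """Seeded k-means microstate discretization.

    Returns ``(dtrajs, ClusterModel)``; every frame is assigned and the
    result is deterministic given the seed.
    """
    trajs = _as_traj_list(projections)
    X = np.vstack([np.atleast_2d(t.T).T if t.ndim == 1 else t for t in trajs])
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        raise InvalidParameterError("empty input")
    if k > X.shape[0]:
        raise InvalidParameterError("more clusters than frames")
    if k == X.shape[0]:
        # each frame its own microstate, in frame order
        labels = np.arange(X.shape[0])
        centers = X.copy()
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=5).fit(X)
        labels, centers = km.labels_, km.cluster_centers_
    dtrajs, pos = [], 0
    for t in trajs:
        ln = t.shape[0]
        dtrajs.append(labels[pos:pos + ln].astype(int))
        pos += ln
    return dtrajs, ClusterModel(centers=centers)


# ---------------------------------------------------------------------------
# transition-matrix estimation
# ---------------------------------------------------------------------------


def count_matrix(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag; trajectories
    shorter than lag+1 contribute nothing."""
    if lag < 1:
        raise InvalidParameterError("lag must be >= 1")
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if n_states is None:
        n_states = max((int(d.max()) for d in dtrajs if d.size), default=-1) + 1
    C = np.zeros((n_states, n_states))
    for d in dtrajs:
        if d.shape[0] < lag + 1:
            continue
        np.add.at(C, (d[:-lag], d[lag:]), 1.0)
    return C


def largest_connected_set(C: np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph."""
    adj = scipy.sparse.csr_matrix(C > 0)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    best, best_key = None, (-1, -1.0)
    for c in range(n_comp):
        states = np.nonzero(labels == c)[0]
        key = (states.size, C[np.ix_(states, states)].sum())
        if key > best_key:
            best, best_key = states, key
    if best is None or best_key[1] == 0:
        raise EstimationError("empty connected set: no transition counts")
    return best


def _reversible_mle(C: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000):
    """Detailed-balance-constrained maximum likelihood by fixed-point
    iteration on the symmetric flux matrix X (X_ij proportional to
    pi_i T_ij)."""
    c_row = C.sum(axis=1)
    X = C + C.T
    X = X / X.sum()
    Csym = C + C.T
    for _ in range(max_iter):
        x = X.sum(axis=1)
        denom = (c_row / x)[:, None] + (c_row / x)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            Xn = np.where(Csym > 0, Csym / denom, 0.0)
        Xn = Xn / Xn.sum()
        delta = np.abs(Xn - X).max()
        X = Xn
        if delta < tol:
            break
    x = X.sum(axis=1)
    T = X / x[:, None]
    pi = x / x.sum()
    return T, pi


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized."""
    evals, evecs = scipy.linalg.eig(T.T)
    k = np.argmin(np.abs(evals - 1.0))
    pi = np.real(evecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class MSMModel:
    lag: int
    active_set: np.ndarray  # original microstate labels
    T: np.ndarray  # row-stochastic over active set
    pi: np.ndarray
    reversible: bool
    counts: np.ndarray = field(repr=False, default=None)
    n_states_full: int = 0

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        if self.reversible:
            d = np.sqrt(self.pi)
            S = (self.T * d[:, None]) / d[None, :]
            ev = scipy.linalg.eigvalsh((S + S.T) / 2)[::-1]
        else:
            ev = np.real(scipy.linalg.eigvals(self.T))
            ev = ev[np.argsort(-ev)]
        return ev if k is None else ev[:k]

    def active_index(self) -> dict[int, int]:
        return {int(s): i for i, s in enumerate(self.active_set)}


def estimate_msm(dtrajs, lag: int, reversible: bool = True,
                 n_states: int | None = None) -> MSMModel:
    """Estimate a (reversible) MSM at the given lag.

    Sliding-window counts; only trajectories at least ``lag + 1`` frames long
    are used; the largest strongly connected set is retained; the reversible
    maximum-likelihood transition matrix satisfies detailed balance and its
    stationary distribution is returned alongside.
    """
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    usable = [d for d in dtrajs if d.shape[0] >= lag + 1]
    if not usable:
        raise EstimationError("no trajectory is at least as long as the MSM lag time")
    C_full = count_matrix(usable, lag, n_states=n_states)
    active = largest_connected_set(C_full)
    C = C_full[np.ix_(active, active)]
    if reversible:
        T, pi = _reversible_mle(C)
    else:
        T = C / C.sum(axis=1, keepdims=True)
        pi = stationary_distribution(T)
    return MSMModel(lag=int(lag), active_set=active, T=T, pi=pi,
                    reversible=reversible, counts=C,
                    n_states_full=C_full.shape[0])


# ---------------------------------------------------------------------------
# implied timescales
# ---------------------------------------------------------------------------


@dataclass
class ITSResult:
    lags: np.ndarray
    timescales: np.ndarray  # (n_lags, n_timescales); NaN where eigenvalue <= 0
    negative_eigenvalue: np.ndarray  # bool flags, same shape
    converged: np.ndarray  # (n_timescales,) verdicts
    tol: float


def implied_timescales(dtrajs, lags, n_timescales: int = 2,
                       reversible: bool = True, tol: float = 0.1) -> ITSResult:
    """Implied timescales ``t_k(tau) = -tau / ln(lambda_{k+1}(tau))``.

    A timescale is judged converged when its relative change over the upper
    half of the lag ladder stays below ``tol``.
    """
    lags = np.asarray(sorted(int(x) for x in lags))
    if np.any(lags < 1):
        raise InvalidParameterError("all lags must be >= 1")
    ts = np.full((lags.size, n_timescales), np.nan)
    neg = np.zeros_like(ts, dtype=bool)
    for li, lag in enumerate(lags):
        model = estimate_msm(dtrajs, lag, reversible=reversible)
        if n_timescales > model.T.shape[0] - 1:
            raise InvalidParameterError(
                f"n_timescales={n_timescales} exceeds active states - 1 "
                f"({model.T.shape[0] - 1}) at lag {lag}"
            )
        ev = model.eigenvalues(n_timescales + 1)[1:]
        for k, lam in enumerate(ev):
            if lam <= 0 or lam >= 1:
                neg[li, k] = lam <= 0
                ts[li, k] = np.nan if lam <= 0 else np.inf
            else:
                ts[li, k] = -lag / np.log(lam)
    upper = ts[lags.size // 2:]
    converged = np.zeros(n_timescales, dtype=bool)
    for k in range(n_timescales):
        col = upper[:, k]
        col = col[np.isfinite(col)]
        if col.size >= 2 and col.min() > 0:
            converged[k] = (col.max() - col.min()) / col.mean() < tol
    return ITSResult(lags=lags, timescales=ts, negative_eigenvalue=neg,
                     converged=converged, tol=tol)


# ---------------------------------------------------------------------------
# VAMP-2
# ---------------------------------------------------------------------------


def vamp2_score(dtrajs, lag: int, rank: int | None = None) -> float:
    """VAMP-2 score of a discretization at the given lag.

    Sum of squared singular values of the covariance-whitened transition
    operator built from indicator functions on the microstates, truncated at
    ``rank`` (constant singular function included, so the score is >= 1 for
    equilibrium data)."""
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    n_states = max(int(d.max()) for d in dtrajs if d.size) + 1
    C01 = count_matrix(dtrajs, lag, n_states=n_states)
    c0 = C01.sum(axis=1)
    c1 = C01.sum(axis=0)
    keep = (c0 > 0) & (c1 > 0)
    if not np.any(keep):
        raise EstimationError("no usable transition pairs at this lag")
    K = C01[np.ix_(keep, keep)] / np.sqrt(np.outer(c0[keep], c1[keep]))
    sv = scipy.linalg.svdvals(K)
    avail = sv.size
    if rank is None:
        rank = avail
    if rank < 1:
        raise InvalidParameterError("rank must be >= 1")
    if rank > avail:
        warnings.warn(f"rank {rank} exceeds available states ({avail}); clipped")
        rank = avail
    return float(np.sum(sv[:rank] ** 2))


def vamp2_from_transition_matrix(T: np.ndarray, pi: np.ndarray | None = None,
                                 rank: int | None = None) -> float:
    """VAMP-2 score of an exact transition matrix at its stationary
    distribution; for a reversible T this equals ``1 + sum_k lambda_k^2``
    over the non-unit eigenvalues."""
    T = np.asarray(T, dtype=float)
    if pi is None:
        pi = stationary_distribution(T)
    d = np.sqrt(pi)
    K = (T * d[:, None]) / d[None, :]
    sv = scipy.linalg.svdvals(K)
    if rank is not None:
        sv = sv[:rank]
    return float(np.sum(sv**2))


# ---------------------------------------------------------------------------
# hyperparameter grid search
# ---------------------------------------------------------------------------


def grid_search(features, grid: dict, msm_lag: int, seed: int = 0,
                rank: int | None = None, regularization: float = 1e-10) -> pd.DataFrame:
    """Exhaustive VAMP-2 grid search over discretization hyperparameters.

    ``grid`` maps ``k_clusters``, ``n_tics`` and ``tica_lag`` to candidate
    lists.  Rows are ranked by descending score with ties broken by fewer
    clusters, then fewer tICs.
    """
    ks = list(grid.get("k_clusters", [100]))
    tics = list(grid.get("n_tics", [2]))
    tlags = list(grid.get("tica_lag", [1]))
    if not (ks and tics and tlags):
        raise InvalidParameterError("empty hyperparameter grid")
    rows, failures = [], []
    for tlag in tlags:
        for n_tic in tics:
            try:
                model = tica_fit(features, lag=tlag, n_components=n_tic,
                                 regularization=regularization)
                proj = model.transform(features)
            except Exception as exc:  # noqa: BLE001 - aggregated below
                failures.append(f"tica(lag={tlag}, n_tics={n_tic}): {exc}")
                continue
            for k in ks:
                try:
                    dtrajs, _ = cluster_microstates(proj, k=k, seed=seed)
                    score = vamp2_score(dtrajs, lag=msm_lag, rank=rank)
                    rows.append({"k_clusters": k, "n_tics": n_tic,
                                 "tica_lag": tlag, "vamp2": score})
                except Exception as exc:  # noqa: BLE001
                    failures.append(f"(k={k}, n_tics={n_tic}, tica_lag={tlag}): {exc}")
    if not rows:
        raise EstimationError("all grid combinations failed: " + "; ".join(failures))
    table = pd.DataFrame(rows).sort_values(
        by=["vamp2", "k_clusters", "n_tics"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# frame weights and reweighting validation
# ---------------------------------------------------------------------------


def _active_counts(model: MSMModel, dtrajs) -> np.ndarray:
    n_full = max(model.n_states_full, int(max(d.max() for d in dtrajs if d.size)) + 1)
    counts_full = np.zeros(n_full)
    for d in dtrajs:
        counts_full += np.bincount(d, minlength=n_full)
    return counts_full[model.active_set]


def frame_weights(model: MSMModel, dtrajs) -> list[np.ndarray]:
    """Equilibrium weight per frame: ``pi_i / N_i`` for frames in active
    microstate i, zero outside the active set; weights sum to 1."""
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    counts = _active_counts(model, dtrajs)
    per_state = np.zeros_like(counts)
    nonzero = counts > 0
    per_state[nonzero] = model.pi[nonzero] / counts[nonzero]
    total = model.pi[nonzero].sum()
    n_full = max(model.n_states_full, int(max(d.max() for d in dtrajs if d.size)) + 1)
    lookup = np.zeros(n_full)
    lookup[model.active_set] = per_state / total
    return [lookup[d] for d in dtrajs]


@dataclass
class ReweightReport:
    raw_fraction: np.ndarray
    stationary: np.ndarray
    slope: float
    intercept: float
    max_log10_ratio: float
    passed: bool


def reweighting_validation(dtrajs, model: MSMModel, slope_tol: float = 0.25,
                           log_ratio_tol: float = 0.5) -> ReweightReport:
    """Raw microstate populations versus MSM stationary probabilities.

    Well-sampled equilibrium data should put the points on x = y; the report
    carries a robust (Theil--Sen) fit and the worst log10 population ratio.
    """
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    counts = _active_counts(model, dtrajs)
    if counts.sum() == 0:
        raise EstimationError("no frames in the active set")
    raw = counts / counts.sum()
    pi = model.pi
    ok = (raw > 0) & (pi > 0)
    max_log = float(np.abs(np.log10(pi[ok] / raw[ok])).max())
    if np.unique(raw).size > 1:
        fit = scipy.stats.theilslopes(pi, raw)
        slope, intercept = float(fit[0]), float(fit[1])
    else:
        slope, intercept = 1.0, 0.0
    passed = (abs(slope - 1.0) <= slope_tol) and (max_log <= log_ratio_tol)
    return ReweightReport(raw_fraction=raw, stationary=pi, slope=slope,
                          intercept=intercept, max_log10_ratio=max_log,
                          passed=passed)


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------


@dataclass
class CKResult:
    macrostates: list[np.ndarray]  # active-set indices per macrostate
    factors: list[int]
    predicted: dict  # factor -> (m, m) set-to-set probabilities
    estimated: dict
    bands: dict  # factor -> (lo, hi) arrays
    fraction_within: float
    passed: bool
    skipped_factors: list[int]


def _macrostate_sets(model: MSMModel, n_macrostates: int, seed: int):
    """Metastable lumping: k-means on the components of the top
    ``n_macrostates - 1`` non-trivial right eigenvectors of T."""
    n = model.T.shape[0]
    if n_macrostates > n:
        raise InvalidParameterError("more macrostates than active microstates")
    if n_macrostates == n:
        return [np.array([i]) for i in range(n)]
    d = np.sqrt(model.pi)
    S = (model.T * d[:, None]) / d[None, :]
    evals, evecs = scipy.linalg.eigh((S + S.T) / 2)
    order = np.argsort(evals)[::-1]
    # right eigenvectors of T: D^{-1/2} u
    psi = evecs[:, order[1:n_macrostates]] / d[:, None]
    km = KMeans(n_clusters=n_macrostates, random_state=seed, n_init=10).fit(psi)
    return [np.nonzero(km.labels_ == c)[0] for c in range(n_macrostates)]


def _set_probabilities(T: np.ndarray, pi: np.ndarray, sets) -> np.ndarray:
    m = len(sets)
    P = np.zeros((m, m))
    for a, sa in enumerate(sets):
        wa = pi[sa]
        if wa.sum() == 0:
            P[a] = np.nan
            continue
        flux = wa @ T[sa]  # weighted outgoing distribution
        for b, sb in enumerate(sets):
            P[a, b] = flux[sb].sum() / wa.sum()
    return P


def _project_sets(sets_labels: list[np.ndarray], model: MSMModel):
    """Macrostate sets given as original microstate labels -> active indices."""
    idx = model.active_index()
    return [np.array([idx[int(s)] for s in labels if int(s) in idx], dtype=int)
            for labels in sets_labels]


def ck_test(dtrajs, model: MSMModel, n_macrostates: int = 2,
            factors=(2, 3), n_bootstrap: int = 50, seed: int = 0,
            conf: float = 0.95, macrostate_sets=None) -> CKResult:
    """Chapman--Kolmogorov test with bootstrap confidence bands.

    Compares the set-to-set probabilities predicted by ``T(tau)^k`` against
    those re-estimated at lag ``k * tau``; the test passes when predictions
    fall inside the bootstrap bands for at least ``conf`` of all points.
    Factors whose lag exceeds every trajectory are skipped with a warning.
    """
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if macrostate_sets is None:
        sets = _macrostate_sets(model, n_macrostates, seed)
        sets_labels = [model.active_set[s] for s in sets]
    else:
        sets_labels = [np.asarray(s, dtype=int) for s in macrostate_sets]
        sets = _project_sets(sets_labels, model)
    rng = np.random.default_rng(seed)
    predicted, estimated, bands = {}, {}, {}
    skipped = []
    lo_q, hi_q = 100 * (1 - conf) / 2, 100 * (1 + conf) / 2
    for k in factors:
        if k < 2:
            raise InvalidParameterError("CK factors must be >= 2")
        lag_k = model.lag * k
        if not any(d.shape[0] >= lag_k + 1 for d in dtrajs):
            warnings.warn(f"factor {k}: no trajectory long enough; skipped")
            skipped.append(k)
            continue
        Tk = np.linalg.matrix_power(model.T, k)
        predicted[k] = _set_probabilities(Tk, model.pi, sets)
        est_model = estimate_msm(dtrajs, lag_k, reversible=model.reversible)
        est_sets = _project_sets(sets_labels, est_model)
        estimated[k] = _set_probabilities(est_model.T, est_model.pi, est_sets)
        samples = []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, len(dtrajs), size=len(dtrajs))
            try:
                bm = estimate_msm([dtrajs[i] for i in pick], lag_k,
                                  reversible=model.reversible)
            except EstimationError:
                continue
            bs = _project_sets(sets_labels, bm)
            samples.append(_set_probabilities(bm.T, bm.pi, bs))
        if not samples:
            warnings.warn(f"factor {k}: all bootstrap re-estimates failed; skipped")
            skipped.append(k)
            predicted.pop(k), estimated.pop(k)
            continue
        arr = np.array(samples)
        bands[k] = (np.nanpercentile(arr, lo_q, axis=0),
                    np.nanpercentile(arr, hi_q, axis=0))
    n_pts, n_in = 0, 0
    for k in predicted:
        lo, hi = bands[k]
        P = predicted[k]
        ok = np.isfinite(P) & np.isfinite(lo) & np.isfinite(hi)
        n_pts += int(ok.sum())
        n_in += int(((P >= lo - 1e-12) & (P <= hi + 1e-12) & ok).sum())
    frac = n_in / n_pts if n_pts else np.nan
    return CKResult(macrostates=sets, factors=list(predicted), predicted=predicted,
                    estimated=estimated, bands=bands,
                    fraction_within=float(frac),
                    passed=bool(n_pts and frac >= conf), skipped_factors=skipped)


# ---------------------------------------------------------------------------
# simulation from an exact chain (used widely in validation)
# ---------------------------------------------------------------------------


def simulate_chain(T: np.ndarray, n_steps: int, seed: int = 0,
                   start: int | None = None) -> np.ndarray:
    """Sample a discrete trajectory from an exact Markov chain."""
    T = np.asarray(T, dtype=float)
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    cdf = np.cumsum(T, axis=1)
    out = np.empty(n_steps, dtype=int)
    s = int(start) if start is not None else int(rng.integers(n))
    u = rng.random(n_steps)
    for i in range(n_steps):
        out[i] = s
        s = int(np.searchsorted(cdf[s], u[i]))
    return out
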