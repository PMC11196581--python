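"""MSM-weighted 2-D free-energy landscapes, minima/barrier extraction, and
bootstrap error landscapes.

``dG_bin = -kT ln(p_bin / p_max)`` with p the (MSM-)weighted histogram, so
the global minimum is at 0 kcal/mol; empty bins are masked (NaN), never 0.
The bootstrap error procedure re-estimates the MSM on random trajectory
subsets drawn without replacement (at trajectory granularity) against a
fixed clustering and binning, and reports the per-bin standard deviation of
dG across subsets.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from . import msm as _msm
from .errors import (
    DisconnectedError,
    EmptyLandscapeError,
    GridMismatchError,
    InvalidParameterError,
    NoMinimaError,
)
from .features import local_minima_bins
from .toysim import KT_300K


@dataclass
class LandscapeGrid:
    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny) kcal/mol; NaN on empty bins
    kT: float
    counts: np.ndarray = None  # raw frame counts per bin
    effective_samples: np.ndarray = None  # Kish effective sample size per bin

    @property
    def shape(self):
        return self.free_energy.shape

    def probability(self) -> np.ndarray:
        """Reconstruct the normalized bin probabilities."""
        p = np.exp(-np.nan_to_num(self.free_energy, nan=np.inf) / self.kT)
        p[~np.isfinite(self.free_energy)] = 0.0
        return p / p.sum()

    def assign(self, x, y) -> np.ndarray:
        """Per-frame (ix, iy) bin indices; -1 outside the grid."""
        ix = np.searchsorted(self.x_edges, x, side="right") - 1
        iy = np.searchsorted(self.y_edges, y, side="right") - 1
        ix = np.where((x == self.x_edges[-1]), len(self.x_edges) - 2, ix)
        iy = np.where((y == self.y_edges[-1]), len(self.y_edges) - 2, iy)
        bad = (ix < 0) | (ix >= self.shape[0]) | (iy < 0) | (iy >= self.shape[1])
        out = np.stack([ix, iy], axis=1).astype(int)
        out[bad] = -1
        return out


def _edges(series, bins, pad: float = 0.02):
    lo, hi = float(np.min(series)), float(np.max(series))
    span = hi - lo or 1.0
    return np.linspace(lo - pad * span, hi + pad * span, bins + 1)


def free_energy_landscape(
    x_series, y_series, weights=None, bins=60, kT: float = KT_300K,
    x_name: str = "x", y_name: str = "y", edges=None,
) -> LandscapeGrid:
    """Weighted 2-D free-energy surface relative to its global minimum.

    ``bins`` may be an int (applied to both axes over the observed range
    padded by 2%) or a pair; explicit ``edges=(x_edges, y_edges)`` overrides.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("x and y series must have equal length")
    if weights is None:
        weights = np.ones_like(x)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise InvalidParameterError("weights must be non-negative")
    if w.sum() == 0:
        raise EmptyLandscapeError("all weights are zero")
    if edges is not None:
        x_edges, y_edges = (np.asarray(e, dtype=float) for e in edges)
    else:
        nx, ny = (bins, bins) if np.isscalar(bins) else bins
        x_edges, y_edges = _edges(x, nx), _edges(y, ny)
    p, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=w)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    w2, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=w**2)
    if p.sum() == 0:
        raise EmptyLandscapeError("no frame fell inside the binned region")
    with np.errstate(divide="ignore", invalid="ignore"):
        G = -kT * np.log(p / p.max())
        ess = np.where(w2 > 0, p**2 / w2, 0.0)
    G[p <= 0] = np.nan
    return LandscapeGrid(x_name=x_name, y_name=y_name, x_edges=x_edges,
                         y_edges=y_edges, free_energy=G, kT=kT,
                         counts=counts, effective_samples=ess)


# ---------------------------------------------------------------------------
# minima and barriers
# ---------------------------------------------------------------------------


def find_minima_and_barrier(grid: LandscapeGrid, state_a, state_b):
    """Local minima plus the barrier from ``state_a`` toward ``state_b``.

    Minima are strict 8-neighborhood minima over finite bins.  The barrier
    is the minimax path height over 8-connected finite bins minus
    ``dG(state_a)``.  ``state_a``/``state_b`` are bin index pairs; they are
    snapped to the nearest local minimum.
    """
    G = grid.free_energy
    finite = np.isfinite(G)
    minima = local_minima_bins(G)
    if len(minima) < 2:
        # an entirely flat landscape has no strict minima but a trivial
        # barrier of 0 between any two finite bins
        if finite.any() and np.nanmax(G) == np.nanmin(G):
            return [], 0.0
        raise NoMinimaError("need at least two local minima for a barrier")

    def snap(state):
        state = tuple(int(v) for v in state)
        return min(minima, key=lambda m: (m[0] - state[0]) ** 2 + (m[1] - state[1]) ** 2)

    a, b = snap(state_a), snap(state_b)
    # minimax (widest-path) Dijkstra over finite bins
    nx, ny = G.shape
    best = np.full((nx, ny), np.inf)
    best[a] = G[a]
    heap = [(G[a], a)]
    while heap:
        h, (i, j) = heapq.heappop(heap)
        if h > best[i, j]:
            continue
        if (i, j) == b:
            break
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ii, jj = i + di, j + dj
                if not (0 <= ii < nx and 0 <= jj < ny):
                    continue
                if not np.isfinite(G[ii, jj]):
                    continue
                nh = max(h, G[ii, jj])
                if nh < best[ii, jj]:
                    best[ii, jj] = nh
                    heapq.heappush(heap, (nh, (ii, jj)))
    if not np.isfinite(best[b]):
        raise DisconnectedError(f"states {a} and {b} not connected on finite bins")
    return minima, float(best[b] - G[a])


# ---------------------------------------------------------------------------
# bootstrap error landscapes
# ---------------------------------------------------------------------------


@dataclass
class BootstrapError:
    x_edges: np.ndarray
    y_edges: np.ndarray
    error: np.ndarray  # per-bin SD of dG across subsets; NaN where < 2 finite
    n_subsets: int
    n_dropped: int
    subset_fraction: float
    seed: int


def bootstrap_error_landscape(
    observables, dtrajs, msm_lag: int, bins_or_edges, n_subsets: int = 200,
    frac: float = 0.8, seed: int = 0, kT: float = KT_300K,
    reversible: bool = True,
) -> BootstrapError:
    """Sampling-error landscape from trajectory-subset MSMs.

    ``observables`` is a list of per-trajectory ``(x, y)`` pairs aligned with
    ``dtrajs`` (assignments from the shared cluster model).  Each subset
    draws ``frac`` of the trajectories without replacement, re-estimates the
    MSM at ``msm_lag``, rebuilds the landscape on the fixed bins, and the
    per-bin standard deviation of dG across subsets is reported.
    """
    if n_subsets < 2:
        raise InvalidParameterError("n_subsets must be >= 2")
    if not (0 < frac < 1):
        raise InvalidParameterError("frac must be in (0, 1)")
    n_traj = len(dtrajs)
    if len(observables) != n_traj:
        raise GridMismatchError("observables and dtrajs must align per trajectory")
    if isinstance(bins_or_edges, tuple) and not np.isscalar(bins_or_edges[0]):
        x_edges, y_edges = (np.asarray(e, dtype=float) for e in bins_or_edges)
    else:
        all_x = np.concatenate([np.asarray(o[0], dtype=float) for o in observables])
        all_y = np.concatenate([np.asarray(o[1], dtype=float) for o in observables])
        nx, ny = (bins_or_edges, bins_or_edges) if np.isscalar(bins_or_edges) else bins_or_edges
        x_edges, y_edges = _edges(all_x, nx), _edges(all_y, ny)
    m = max(1, int(round(frac * n_traj)))
    rng = np.random.default_rng(seed)
    stack, dropped = [], 0
    for _ in range(n_subsets):
        pick = rng.choice(n_traj, size=m, replace=False)
        sub_d = [dtrajs[i] for i in pick]
        try:
            model = _msm.estimate_msm(sub_d, msm_lag, reversible=reversible)
            w = _msm.frame_weights(model, sub_d)
        except Exception:  # noqa: BLE001 - subset with empty connected set
            dropped += 1
            continue
        x = np.concatenate([np.asarray(observables[i][0], dtype=float) for i in pick])
        y = np.concatenate([np.asarray(observables[i][1], dtype=float) for i in pick])
        try:
            grid = free_energy_landscape(x, y, np.concatenate(w), kT=kT,
                                         edges=(x_edges, y_edges))
        except EmptyLandscapeError:
            dropped += 1
            continue
        stack.append(grid.free_energy)
    if len(stack) < 2:
        raise InvalidParameterError("fewer than 2 usable subsets")
    arr = np.array(stack)
    finite = np.isfinite(arr)
    n_fin = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(finite, arr, 0.0), axis=0) / np.maximum(n_fin, 1)
        var = np.nansum(np.where(finite, (arr - mean) ** 2, 0.0), axis=0) / np.maximum(
            n_fin, 1
        )
    sd = np.sqrt(var)
    sd[n_fin < 2] = np.nan
    return BootstrapError(x_edges=x_edges, y_edges=y_edges, error=sd,
                          n_subsets=len(stack), n_dropped=dropped,
                          subset_fraction=frac, seed=int(seed))


# ---------------------------------------------------------------------------
# landscape comparison (used by the sampling convergence rule)
# ---------------------------------------------------------------------------


def landscape_difference(a: LandscapeGrid, b: LandscapeGrid):
    """Mean |dG_a - dG_b| over mutually finite bins plus the relative growth
    of the finite-bin set from a to b."""
    if a.shape != b.shape or not np.allclose(a.x_edges, b.x_edges) or not np.allclose(
        a.y_edges, b.y_edges
    ):
        raise GridMismatchError("landscapes must share the same binning")
    fa, fb = np.isfinite(a.free_energy), np.isfinite(b.free_energy)
    both = fa & fb
    if not both.any():
        return np.inf, 1.0
    mean_dev = float(np.abs(a.free_energy[both] - b.free_energy[both]).mean())
    growth = float((fb & ~fa).sum() / max(fa.sum(), 1))
    return mean_dev, growth


def landscape_to_long_dataframe(grid: LandscapeGrid):
    """Long-format (x_bin, y_bin, value) table of a landscape grid."""
    import pandas as pd

    nx, ny = grid.shape
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    return pd.DataFrame({
        "x_bin": ix.ravel(), "y_bin": iy.ravel(),
        "x_center": xc[ix.ravel()], "y_center": yc[iy.ravel()],
        "free_energy": grid.free_energy.ravel(),
    })
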