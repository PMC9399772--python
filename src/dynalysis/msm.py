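"""Markov state models on 2-D collective-variable projections.

Pipeline: k-means microstate clustering of the CV plane, transition-count
estimation at a lag time, a symmetrized (reversible) transition-matrix
estimator, implied-timescale curves t_i = -tau / ln|lambda_i(tau)|,
Perron-cluster coarse-graining into metastable macrostates, the
Chapman-Kolmogorov self-consistency test, and medoid representative-frame
extraction.

The estimator symmetrizes the count matrix, (C + C^T)/2, before row
normalization.  This enforces detailed balance exactly and coincides with
the reversible maximum-likelihood estimator on well-sampled reversible data;
eigenvalues are computed through the pi-weighted symmetric form, so the
spectrum is guaranteed real.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .io import Ensemble, Selection
from .metrics import kabsch

__all__ = [
    "MicrostateModel",
    "TransitionModel",
    "MacrostatePartition",
    "cluster_microstates",
    "estimate_transitions",
    "implied_timescales",
    "coarse_grain",
    "ck_test",
    "representative_structure",
]


@dataclass
class MicrostateModel:
    centers: np.ndarray          # (k, 2)
    assignments: np.ndarray      # (n_frames,), int
    seed: int

    @property
    def n_states(self) -> int:
        return len(self.centers)


@dataclass
class TransitionModel:
    lag_frames: int
    lag_time: float                    # in trajectory time units (ns)
    count_matrix: np.ndarray           # raw (unsymmetrized) counts, full state set
    transition_matrix: np.ndarray      # row-stochastic, active set only
    active_states: np.ndarray          # original state ids of the active set
    stationary: np.ndarray             # pi over active set
    eigenvalues: np.ndarray            # real, sorted descending by modulus

    def implied_timescales(self, n: int = 5) -> np.ndarray:
        """t_i = -tau/ln|lambda_i| in lag-time units, for i = 2..n+1.

        Eigenvalues with |lambda| >= 1 or <= 0 yield NaN (below resolution /
        not a relaxation process).
        """
        lam = self.eigenvalues[1:n + 1]
        out = np.full(n, np.nan)
        ok = (np.abs(lam) < 1.0) & (np.abs(lam) > 0.0)
        out[:len(lam)][ok] = -self.lag_time / np.log(np.abs(lam[ok]))
        return out


@dataclass
class MacrostatePartition:
    n_macrostates: int
    memberships: np.ndarray       # microstate (active set position) -> macrostate
    populations: np.ndarray       # per macrostate, sums to 1
    active_states: np.ndarray     # original microstate ids


# ---------------------------------------------------------------------------

def cluster_microstates(projections: np.ndarray, k: int = 100,
                        seed: int = 0) -> MicrostateModel:
    """k-means clustering of 2-D CV points into microstates (k-means++ init)."""
    pts = np.asarray(projections, dtype=float)
    if pts.ndim != 2:
        raise ValueError("projections must be (n_frames, n_cv)")
    if k > len(np.unique(pts, axis=0)):
        raise ValueError(f"k={k} exceeds the number of distinct points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=500,
                tol=1e-8, random_state=seed)
    labels = km.fit_predict(pts)
    return MicrostateModel(km.cluster_centers_, labels, seed)


def _count_matrix(assignments: np.ndarray, lag: int, n_states: int,
                  boundaries: Optional[Sequence[int]] = None) -> np.ndarray:
    """Sliding transition counts at a lag, not crossing segment boundaries.

    ``boundaries`` are the start indices of each independent trajectory
    segment (replica); default one segment.
    """
    a = np.asarray(assignments, dtype=int)
    starts = [0] if boundaries is None else [int(b) for b in boundaries]
    starts = sorted(set(starts) | {0})
    ends = starts[1:] + [len(a)]
    C = np.zeros((n_states, n_states))
    for s, e in zip(starts, ends):
        seg = a[s:e]
        if len(seg) > lag:
            np.add.at(C, (seg[:-lag], seg[lag:]), 1.0)
    return C


def estimate_transitions(assignments: np.ndarray, lag_frames: int,
                         frame_time: float = 1.0,
                         boundaries: Optional[Sequence[int]] = None,
                         n_states: Optional[int] = None) -> TransitionModel:
    """Reversible transition-matrix estimate at a lag.

    Counts are symmetrized, restricted to the largest connected set, and row
    normalized.  Eigenvalues come from the pi-weighted symmetric form and are
    exactly real.
    """
    a = np.asarray(assignments, dtype=int)
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    ns = int(n_states if n_states is not None else a.max() + 1)
    C = _count_matrix(a, lag_frames, ns, boundaries)
    if C.sum() == 0:
        raise ValueError("no transition counts at this lag")
    Cs = 0.5 * (C + C.T)
    n_comp, comp = connected_components(Cs > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp, weights=Cs.sum(axis=1))
        keep_label = int(np.argmax(sizes))
        active = np.where(comp == keep_label)[0]
    else:
        active = np.arange(ns)
    # drop states never visited at all
    visited = Cs.sum(axis=1) > 0
    active = active[visited[active]]
    Ca = Cs[np.ix_(active, active)]
    rows = Ca.sum(axis=1)
    T = Ca / rows[:, None]
    pi = rows / rows.sum()
    # pi-weighted symmetrization: S = D^{1/2} T D^{-1/2} is symmetric
    s = np.sqrt(pi)
    S = (s[:, None] * T) / s[None, :]
    S = 0.5 * (S + S.T)
    lam = np.linalg.eigvalsh(S)
    lam = lam[np.argsort(np.abs(lam))[::-1]]
    return TransitionModel(lag_frames, lag_frames * frame_time, C, T, active,
                           pi, lam)


def implied_timescales(assignments: np.ndarray, lags: Sequence[int],
                       frame_time: float = 1.0, n_timescales: int = 5,
                       boundaries: Optional[Sequence[int]] = None):
    """Implied-timescale curves t_i(tau) = -tau/ln|lambda_i(tau)|.

    Returns a DataFrame with one row per lag; columns ``lag_frames``,
    ``lag_time`` and ``t_2`` .. ``t_{n+1}`` in the same time units as
    ``frame_time``.  Lags where the chain is disconnected are flagged in the
    ``connected`` column rather than failing.
    """
    import pandas as pd
    rows = []
    ns = int(np.max(assignments)) + 1
    for lag in lags:
        if lag < 1 or lag >= len(assignments):
            raise ValueError(f"lag {lag} outside trajectory length")
        try:
            model = estimate_transitions(assignments, lag, frame_time,
                                         boundaries, n_states=ns)
            its = model.implied_timescales(n_timescales)
            connected = len(model.active_states) == len(
                np.unique(assignments))
        except ValueError:
            its = np.full(n_timescales, np.nan)
            connected = False
        row = {"lag_frames": lag, "lag_time": lag * frame_time,
               "connected": connected}
        row.update({f"t_{i+2}": its[i] for i in range(n_timescales)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coarse graining (Perron-cluster analysis)
# ---------------------------------------------------------------------------

def coarse_grain(model: TransitionModel, n_macrostates: int) -> MacrostatePartition:
    """Crisp Perron-cluster lumping of microstates into metastable sets.

    Microstates are embedded in the space of the top ``n_macrostates`` right
    eigenvectors of T (computed via the pi-weighted symmetric form) and
    clustered with seeded k-means; this is the crisp variant of
    PCCA-style spectral lumping.
    """
    T = model.transition_matrix
    n = T.shape[0]
    if n_macrostates < 1 or n_macrostates > n:
        raise ValueError("n_macrostates must be in [1, n_microstates]")
    if n_macrostates == 1:
        member = np.zeros(n, dtype=int)
        return MacrostatePartition(1, member, np.array([1.0]),
                                   model.active_states)
    pi = model.stationary
    s = np.sqrt(pi)
    S = (s[:, None] * T) / s[None, :]
    S = 0.5 * (S + S.T)
    w, v = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    gap_ok = n_macrostates <= n and (
        n_macrostates == n or
        w[n_macrostates - 1] - w[n_macrostates] > 1e-12)
    if not gap_ok:
        warnings.warn("no clear spectral gap at the requested number of "
                      "macrostates")
    # right eigenvectors of T: psi_i = v_i / sqrt(pi)
    psi = v[:, :n_macrostates] / s[:, None]
    km = KMeans(n_clusters=n_macrostates, n_init=10, random_state=0)
    member = km.fit_predict(psi)
    pops = np.array([pi[member == m].sum() for m in range(n_macrostates)])
    # order macrostates by decreasing population for stable naming
    order = np.argsort(pops)[::-1]
    relabel = np.empty_like(order)
    relabel[order] = np.arange(n_macrostates)
    member = relabel[member]
    pops = pops[order]
    return MacrostatePartition(n_macrostates, member, pops,
                               model.active_states)


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

def _aggregate_self_transition(T: np.ndarray, pi: np.ndarray,
                               sets: Sequence[np.ndarray]) -> np.ndarray:
    out = np.empty(len(sets))
    for m, s in enumerate(sets):
        w = pi[s]
        out[m] = (w[:, None] * T[np.ix_(s, s)]).sum() / w.sum()
    return out


def ck_test(assignments: np.ndarray, partition: MacrostatePartition,
            lag_frames: int, factors: Sequence[int] = (2, 3, 4, 5),
            frame_time: float = 1.0,
            boundaries: Optional[Sequence[int]] = None,
            n_bootstrap: int = 50, n_blocks: int = 50, seed: int = 0,
            ci: float = 0.95):
    """Chapman-Kolmogorov test on macrostate self-transition probabilities.

    Compares [T(tau)^k] aggregated to macrostates (model prediction) with
    T(k tau) estimated directly from the data, for each factor k.  Bootstrap
    confidence intervals for the direct estimate come from resampling
    contiguous trajectory blocks.  Factors whose lag exceeds the data are
    dropped with a warning.
    """
    import pandas as pd
    a = np.asarray(assignments, dtype=int)
    ns = int(a.max()) + 1
    base = estimate_transitions(a, lag_frames, frame_time, boundaries,
                                n_states=ns)
    # map partition (defined on base.active_states) onto state ids
    macro_of_state = {int(s): int(m) for s, m in
                      zip(partition.active_states, partition.memberships)}
    sets = [np.array([i for i, s in enumerate(base.active_states)
                      if macro_of_state.get(int(s)) == m])
            for m in range(partition.n_macrostates)]
    usable = [k for k in factors if k * lag_frames < len(a)]
    if len(usable) < len(factors):
        warnings.warn("some CK factors exceed the trajectory length; truncated")
    rng = np.random.default_rng(seed)
    blocks = np.array_split(np.arange(len(a)), min(n_blocks, len(a)))
    rows = []
    Tk = np.eye(base.transition_matrix.shape[0])
    k_prev = 0
    for k in sorted(usable):
        Tk = np.linalg.matrix_power(base.transition_matrix, k)
        pred = _aggregate_self_transition(Tk, base.stationary, sets)
        direct = estimate_transitions(a, k * lag_frames, frame_time,
                                      boundaries, n_states=ns)
        # align direct model's active set with the base sets
        dsets = [np.array([i for i, s in enumerate(direct.active_states)
                           if macro_of_state.get(int(s)) == m])
                 for m in range(partition.n_macrostates)]
        est = _aggregate_self_transition(direct.transition_matrix,
                                         direct.stationary, dsets)
        # bootstrap over contiguous blocks
        boot = np.full((n_bootstrap, partition.n_macrostates), np.nan)
        for b in range(n_bootstrap):
            pick = rng.integers(0, len(blocks), size=len(blocks))
            idx_blocks = [blocks[p] for p in pick]
            aa = np.concatenate([a[ib] for ib in idx_blocks])
            bnd = np.cumsum([0] + [len(ib) for ib in idx_blocks[:-1]])
            try:
                dm = estimate_transitions(aa, k * lag_frames, frame_time,
                                          boundaries=bnd, n_states=ns)
            except ValueError:
                continue
            bsets = [np.array([i for i, s in enumerate(dm.active_states)
                               if macro_of_state.get(int(s)) == m])
                     for m in range(partition.n_macrostates)]
            if any(len(s) == 0 for s in bsets):
                continue
            boot[b] = _aggregate_self_transition(dm.transition_matrix,
                                                 dm.stationary, bsets)
        alpha = (1.0 - ci) / 2
        lo = np.nanpercentile(boot, 100 * alpha, axis=0)
        hi = np.nanpercentile(boot, 100 * (1 - alpha), axis=0)
        for m in range(partition.n_macrostates):
            rows.append({"factor": k, "lag_time": k * lag_frames * frame_time,
                         "macrostate": m, "predicted": pred[m],
                         "estimated": est[m], "ci_low": lo[m], "ci_high": hi[m],
                         "within_ci": bool(lo[m] - 1e-12 <= pred[m] <= hi[m] + 1e-12)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# representative structures
# ---------------------------------------------------------------------------

def representative_structure(ensemble: Ensemble, frame_labels: np.ndarray,
                             macrostate: int, selection: Selection,
                             max_frames: int = 2000, seed: int = 0) -> int:
    """Medoid frame of a macrostate: minimal mean pairwise Calpha RMSD.

    ``frame_labels`` assigns every frame to a macrostate (or -1 for
    unassigned).  States larger than ``max_frames`` are subsampled
    deterministically.  Returns the frame index in the full ensemble.
    """
    members = np.where(np.asarray(frame_labels) == macrostate)[0]
    if len(members) == 0:
        raise ValueError(f"macrostate {macrostate} has no member frames")
    if len(members) == 1:
        return int(members[0])
    if len(members) > max_frames:
        rng = np.random.default_rng(seed)
        members = np.sort(rng.choice(members, size=max_frames, replace=False))
    sub = ensemble.coordinates[np.ix_(members, list(selection.indices))]
    m = len(members)
    # center all frames once; pairwise Kabsch RMSD
    centered = sub - sub.mean(axis=1, keepdims=True)
    total = np.zeros(m)
    for i in range(m):
        for j in range(i + 1, m):
            R, _, _ = kabsch(centered[j], centered[i])
            d = centered[j] @ R.T - centered[i]
            r = np.sqrt((d ** 2).sum() / sub.shape[1])
            total[i] += r
            total[j] += r
    return int(members[int(np.argmin(total))])
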