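"""Conformational metrics: superposition, RMSD/RMSF, distances, PCA, landscapes.

Conventions
-----------
* Superposition uses the Kabsch least-squares rigid-body fit on a chosen
  atom selection; the default reference is an iteratively refined mean
  structure (fit every frame to the current mean, recompute it, repeat to convergence).
* RMSF is reported per residue via its Calpha (or whichever atoms are
  selected), RMSF_i = sqrt(<|r_i - <r_i>|^2>).
* Free-energy landscapes are Boltzmann inversions of a 2-D histogram,
  F = -kT ln(P / P_max), so the occupied minimum is exactly 0; empty bins
  carry NaN as a sentinel.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import Ensemble, Selection

__all__ = [
    "ScalarSeries",
    "PCAResult",
    "Landscape2D",
    "kabsch",
    "superpose",
    "rmsd_series",
    "rmsf",
    "rmsf_difference",
    "distance_series",
    "pca",
    "free_energy_landscape",
    "KB_KCAL",
]

KB_KCAL = 0.0019872041       # Boltzmann constant, kcal/(mol K)


@dataclass
class ScalarSeries:
    """A named per-frame scalar observable."""

    name: str
    values: np.ndarray
    units: str = "A"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.name!r} contains non-finite values")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std(ddof=0))

    def summary(self) -> str:
        return f"{self.name}: {self.mean:.2f} +/- {self.std:.2f} {self.units}"


@dataclass
class PCAResult:
    eigenvalues: np.ndarray       # A^2, descending
    eigenvectors: np.ndarray      # (3k, n_modes), columns orthonormal
    projections: np.ndarray       # (n_frames, n_modes), centered
    mean_structure: np.ndarray    # (k, 3)

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class Landscape2D:
    cv_names: tuple
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy_kt: np.ndarray        # (nx, ny); NaN marks empty bins
    temperature_K: float

    @property
    def free_energy_kcal(self) -> np.ndarray:
        return self.free_energy_kt * KB_KCAL * self.temperature_K


# ---------------------------------------------------------------------------
# rigid-body superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation R and translation t with R @ mobile_centered ~ ref.

    Returns ``(R, t_mobile, t_ref)`` such that the superposed coordinates are
    ``(x - t_mobile) @ R.T + t_ref``.
    """
    t_m = mobile.mean(axis=0)
    t_r = reference.mean(axis=0)
    H = (mobile - t_m).T @ (reference - t_r)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, t_m, t_r


def _check_noncollinear(coords: np.ndarray) -> None:
    c = coords - coords.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if len(s) < 2 or s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError(
            "superposition selection is collinear or degenerate; need >= 3 "
            "non-collinear atoms")


def superpose(ensemble: Ensemble, selection: Selection,
              reference: "int | str" = "mean") -> Ensemble:
    """Least-squares rigid-body fit of every frame onto a reference.

    ``reference`` is either a frame index or ``"mean"`` (iterative mean
    structure: fit to the current mean, recompute it, repeat to convergence).
    The transform is computed on the selection and applied to all atoms.
    """
    if len(selection) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    coords = ensemble.coordinates.copy()
    idx = list(selection.indices)
    _check_noncollinear(coords[0][idx])

    def fit_to(ref_sel: np.ndarray, frames: np.ndarray) -> np.ndarray:
        out = np.empty_like(frames)
        for f in range(frames.shape[0]):
            R, t_m, t_r = kabsch(frames[f][idx], ref_sel)
            out[f] = (frames[f] - t_m) @ R.T + t_r
        return out

    if reference == "mean":
        for _ in range(50):
            mean_sel = coords[:, idx, :].mean(axis=0)
            new = fit_to(mean_sel, coords)
            shift = np.abs(new - coords).max()
            coords = new
            if shift < 1e-12:
                break
    else:
        ref_sel = coords[int(reference)][idx]
        coords = fit_to(ref_sel, coords)
    return Ensemble(coords, ensemble.frame_times.copy(), ensemble.topology,
                    ensemble.system_label)


# ---------------------------------------------------------------------------
# RMSD / RMSF / distances
# ---------------------------------------------------------------------------

def rmsd_series(ensemble: Ensemble, selection: Selection,
                reference: int = 0) -> ScalarSeries:
    """Per-frame RMSD (A) of the selection to a reference frame.

    No fitting is performed here; superpose first if a least-squares RMSD is
    wanted.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    sub = ensemble.subset(selection)
    ref = sub[int(reference)]
    diff = sub - ref[None]
    vals = np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))
    return ScalarSeries("rmsd", vals, "A")


def rmsf(ensemble: Ensemble, selection: Selection) -> "pd.DataFrame":
    """Per-atom fluctuation RMSF_i = sqrt(<|r_i - <r_i>|^2>), mapped to residues.

    Returns a DataFrame with columns ``resid``, ``resname``, ``rmsf`` (A),
    one row per selected atom.
    """
    import pandas as pd
    if ensemble.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    if len(selection) == 0:
        raise ValueError("empty selection")
    sub = ensemble.subset(selection)
    mean = sub.mean(axis=0)
    vals = np.sqrt(((sub - mean[None]) ** 2).sum(axis=2).mean(axis=0))
    top = ensemble.topology
    idx = list(selection.indices)
    return pd.DataFrame({
        "resid": top.resids[idx],
        "resname": [str(r) for r in top.resnames[idx]],
        "rmsf": vals,
    })


def rmsf_difference(system_a, system_b) -> "pd.DataFrame":
    """Per-residue RMSF difference (a - b) between two systems.

    Both inputs are RMSF DataFrames as returned by :func:`rmsf`.  The sign
    convention (``delta = rmsf_a - rmsf_b``) is recorded in the ``convention``
    DataFrame attribute.
    """
    import pandas as pd
    a = system_a.reset_index(drop=True)
    b = system_b.reset_index(drop=True)
    if len(a) != len(b) or not (a["resid"].values == b["resid"].values).all():
        only_a = sorted(set(a["resid"]) - set(b["resid"]))
        only_b = sorted(set(b["resid"]) - set(a["resid"]))
        raise ValueError(
            f"residue sets differ (only in a: {only_a}; only in b: {only_b})")
    out = pd.DataFrame({
        "resid": a["resid"].values,
        "resname": a["resname"].values,
        "delta_rmsf": a["rmsf"].values - b["rmsf"].values,
    })
    out.attrs["convention"] = "delta = rmsf_a - rmsf_b"
    return out


def distance_series(ensemble: Ensemble, group_i: Selection, group_j: Selection,
                    mode: str = "atom", name: str = "distance") -> ScalarSeries:
    """Per-frame distance (A) between two atoms or two group centroids."""
    if len(group_i) == 0 or len(group_j) == 0:
        raise ValueError("distance groups must be nonempty")
    if mode == "atom":
        if len(group_i) != 1 or len(group_j) != 1:
            raise ValueError("mode='atom' requires single-atom groups")
        a = ensemble.subset(group_i)[:, 0, :]
        b = ensemble.subset(group_j)[:, 0, :]
    elif mode == "centroid":
        a = ensemble.subset(group_i).mean(axis=1)
        b = ensemble.subset(group_j).mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ScalarSeries(name, np.linalg.norm(a - b, axis=1), "A")


# ---------------------------------------------------------------------------
# PCA and free-energy landscapes
# ---------------------------------------------------------------------------

def pca(ensemble: Ensemble, selection: Selection, n_modes: int | None = None) -> PCAResult:
    """Eigendecomposition of the 3k x 3k coordinate covariance of a selection.

    The ensemble should be superposed first.  Projections are centered; the
    eigenvalue sum equals the total positional variance of the selection.
    """
    import warnings as _w
    sub = ensemble.subset(selection)
    nf, k, _ = sub.shape
    x = sub.reshape(nf, 3 * k)
    if nf <= 3 * k:
        _w.warn(f"PCA with {nf} frames and {3*k} coordinates; eigenvalues will "
                "be rank-deficient")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / nf
    if np.allclose(cov, 0):
        raise ValueError("zero-variance coordinates; PCA undefined")
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    if n_modes is not None:
        w, v = w[:n_modes], v[:, :n_modes]
    proj = xc @ v
    return PCAResult(w, v, proj, mean.reshape(k, 3))


def free_energy_landscape(cv1: ScalarSeries, cv2: ScalarSeries,
                          bins: int | Sequence = 50,
                          temperature_K: float = 300.0) -> Landscape2D:
    """Boltzmann inversion of the 2-D histogram of two collective variables.

    F(bin) = -kT ln(P(bin) / P_max) in kT units; the occupied minimum is
    exactly 0 and empty bins are NaN.
    """
    if len(cv1.values) != len(cv2.values):
        raise ValueError("collective-variable series must have equal length")
    if isinstance(bins, int) and bins < 10:
        raise ValueError("use at least 10 bins per axis")
    counts, xe, ye = np.histogram2d(cv1.values, cv2.values, bins=bins)
    if (counts > 0).sum() == 1:
        import warnings as _w
        _w.warn("all frames fall into a single bin; degenerate landscape")
    with np.errstate(divide="ignore"):
        f = -np.log(counts / counts.max())
    f[counts == 0] = np.nan
    return Landscape2D((cv1.name, cv2.name), xe, ye, f, temperature_K)
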