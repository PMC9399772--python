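"""Synthetic trajectory and complex-fixture generators with known ground truth.

Real microsecond MD trajectories of a protein-inhibitor complex are far too
expensive to regenerate, and equilibrium ensembles at that scale are rarely
deposited.  Every analysis stage in this package is therefore validated
against synthetic data whose statistical structure is known exactly:

* :func:`gen_gaussian_ensemble` — i.i.d. frames from a multivariate normal
  with per-component (x, y, z independent) covariance between atoms.  For
  jointly Gaussian fluctuations both the displacement cross-correlation and
  the mutual-information based generalized correlation have closed forms
  (DCCM = r; MI = -(3/2) ln(1 - r^2); GC = |r|), giving exact oracles.
* :func:`gen_markov_ensemble` — a discrete metastable Markov chain emitted
  into a 2-D collective-variable plane with isotropic Gaussian noise, the
  ground truth for transition-matrix, implied-timescale and
  Chapman-Kolmogorov recovery.
* :func:`gen_complex_fixture` — small protein-fragment / ligand / water
  geometries with planted hydrogen bonds, water bridges and solvent-shell
  occupants, emitted together with a ground-truth report so interaction
  analyses can be checked bit-exactly.

All generators are deterministic given their seed.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .io import Ensemble, Topology, write_pdb, write_trajectory

__all__ = [
    "GaussianEnsembleSpec",
    "MarkovEnsembleSpec",
    "ComplexFixtureSpec",
    "HBondPlant",
    "BridgePlant",
    "ShellWaters",
    "gen_gaussian_ensemble",
    "gen_markov_ensemble",
    "gen_complex_fixture",
    "write_fixture",
]


# ---------------------------------------------------------------------------
# Gaussian fluctuation ensembles
# ---------------------------------------------------------------------------

@dataclass
class GaussianEnsembleSpec:
    """Multivariate-normal fluctuation ensemble.

    ``correlations`` lists ``(i, j, r)`` atom pairs whose x, y and z
    displacement components each have Pearson correlation ``r``; unlisted
    pairs are independent.  ``sigma`` is the per-component standard deviation
    in Angstrom (scalar or per atom).
    """

    n_atoms: int
    n_frames: int
    sigma: float | Sequence[float] = 0.5
    correlations: Sequence[tuple] = ()
    mean_coords: Optional[np.ndarray] = None   # (n_atoms, 3), Angstrom
    seed: int = 0

    def covariance(self) -> np.ndarray:
        sig = np.broadcast_to(np.asarray(self.sigma, dtype=float),
                              (self.n_atoms,)).copy()
        if np.any(sig <= 0):
            raise ValueError("sigma must be positive")
        cov = np.diag(sig ** 2)
        for i, j, r in self.correlations:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation r={r} outside [-1, 1]")
            cov[i, j] = cov[j, i] = r * sig[i] * sig[j]
        return cov

    def means(self) -> np.ndarray:
        if self.mean_coords is not None:
            m = np.asarray(self.mean_coords, dtype=float)
            if m.shape != (self.n_atoms, 3):
                raise ValueError("mean_coords must have shape (n_atoms, 3)")
            return m
        # default: beads on a helix (never collinear, so rigid-body
        # superposition against the chain is well conditioned)
        i = np.arange(self.n_atoms, dtype=float)
        m = np.column_stack([4.0 * np.cos(0.8 * i),
                             4.0 * np.sin(0.8 * i),
                             1.5 * i])
        return m


def _ca_chain_topology(n_atoms: int) -> Topology:
    return Topology(
        names=np.array(["CA"] * n_atoms, dtype=object),
        elements=np.array(["C"] * n_atoms, dtype=object),
        resnames=np.array(["ALA"] * n_atoms, dtype=object),
        resids=np.arange(1, n_atoms + 1),
        chainids=np.array(["A"] * n_atoms, dtype=object),
        source="",
    )


def gen_gaussian_ensemble(spec: GaussianEnsembleSpec) -> Ensemble:
    """Draw i.i.d. frames from the multivariate normal defined by ``spec``.

    The x, y and z components are sampled independently, each with the same
    atom-atom covariance matrix, so the planted per-component correlation is
    exactly the displacement-vector cross-correlation of the ensemble.
    """
    cov = spec.covariance()
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("requested covariance is not positive semidefinite")
    L = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(spec.seed)
    # (frames, atoms, 3): each xyz component an independent draw
    z = rng.standard_normal(size=(spec.n_frames, 3, spec.n_atoms))
    fluct = np.einsum("fci,ai->fac", z, L)
    coords = spec.means()[None, :, :] + fluct
    times = 0.1 * np.arange(1, spec.n_frames + 1)
    return Ensemble(coords, times, _ca_chain_topology(spec.n_atoms),
                    system_label=f"gaussian-seed{spec.seed}")


# ---------------------------------------------------------------------------
# Metastable Markov ensembles
# ---------------------------------------------------------------------------

@dataclass
class MarkovEnsembleSpec:
    """Discrete Markov chain emitted into a 2-D collective-variable plane."""

    transition_matrix: np.ndarray       # (n_states, n_states), row-stochastic
    state_centers: np.ndarray           # (n_states, 2), CV-plane coordinates
    noise_sigma: float = 0.1
    n_steps: int = 1000
    seed: int = 0
    start: str = "first"                # "first" | "stationary"

    def validate(self) -> np.ndarray:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0):
            raise ValueError("transition matrix entries must be nonnegative")
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must sum to 1 (tol 1e-12)")
        centers = np.asarray(self.state_centers, dtype=float)
        if centers.shape != (T.shape[0], 2):
            raise ValueError("state_centers must have shape (n_states, 2)")
        if len({tuple(c) for c in centers.tolist()}) != len(centers):
            raise ValueError("state centers must be distinct")
        return T


def _stationary_distribution(T: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def gen_markov_ensemble(spec: MarkovEnsembleSpec):
    """Sample the chain and emit one pseudo-atom at (cv1, cv2, 0) per frame.

    Returns ``(ensemble, labels)`` where ``labels`` is the true hidden state
    of every frame.
    """
    T = spec.validate()
    n_states = T.shape[0]
    rng = np.random.default_rng(spec.seed)
    if spec.start == "stationary":
        n_comp, _ = connected_components(T > 0, directed=True, connection="strong")
        if n_comp > 1:
            raise ValueError(
                "stationary start requested for a reducible chain; the "
                "stationary distribution is not unique")
        pi = _stationary_distribution(T)
        state = int(rng.choice(n_states, p=pi))
    elif spec.start == "first":
        state = 0
    else:
        raise ValueError(f"unknown start mode {spec.start!r}")

    cum = np.cumsum(T, axis=1)
    u = rng.random(spec.n_steps)
    labels = np.empty(spec.n_steps, dtype=int)
    for t in range(spec.n_steps):
        labels[t] = state
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, n_states - 1)
    centers = np.asarray(spec.state_centers, dtype=float)
    cv = centers[labels] + spec.noise_sigma * rng.standard_normal((spec.n_steps, 2))
    coords = np.zeros((spec.n_steps, 1, 3))
    coords[:, 0, :2] = cv
    times = 0.1 * np.arange(1, spec.n_steps + 1)
    top = Topology(
        names=np.array(["CA"], dtype=object),
        elements=np.array(["C"], dtype=object),
        resnames=np.array(["ALA"], dtype=object),
        resids=np.array([1]),
        chainids=np.array(["A"], dtype=object))
    return Ensemble(coords, times, top, f"markov-seed{spec.seed}"), labels


# ---------------------------------------------------------------------------
# Solvated complex fixtures
# ---------------------------------------------------------------------------

_WATER_OH = 0.96            # O-H bond length, Angstrom
_WATER_ANGLE = math.radians(104.5)
_HB_DA = 2.8                # planted donor-acceptor distance, Angstrom
_ABSENT_DA = 6.5            # donor-acceptor distance when bond is "off"
_PARK_OFFSET = np.array([0.0, 0.0, 60.0])   # parking spot for absent waters


@dataclass
class HBondPlant:
    """One donor-H...acceptor triple, present in a chosen subset of frames.

    The donor (an amide-like N-H on the protein fragment) points at a
    dedicated acceptor oxygen; D-H-A is collinear and the D-A distance is
    2.8 A when present, 6.5 A when absent.
    """

    name: str
    present: Optional[Sequence[bool]] = None    # default: all frames
    acceptor_on: str = "ligand"                 # "ligand" | "protein"


@dataclass
class BridgePlant:
    """A protein-water-ligand hydrogen-bond bridge.

    ``bridging_water`` gives, per frame, the index (0-based within this
    plant's water pool) of the water occupying the bridge site, or -1 for no
    bridge.  ``n_waters`` is the pool size.
    """

    name: str
    bridging_water: Sequence[int]
    n_waters: int = 1


@dataclass
class ShellWaters:
    """Waters probing the ligand solvent shell.

    ``n_inside`` (scalar or per frame) of the ``n_total`` waters are placed
    with their O within ``inside_distance`` of the ligand's central atom;
    the rest are parked ~45 A away.  ``distances`` optionally pins explicit
    O-to-central-atom distances for the inside waters (e.g. to sit exactly on
    a shell boundary).
    """

    n_total: int
    n_inside: int | Sequence[int]
    inside_distance: float = 4.0
    distances: Optional[Sequence[float]] = None


@dataclass
class ComplexFixtureSpec:
    n_frames: int
    hbond_plants: Sequence[HBondPlant] = ()
    bridge_plants: Sequence[BridgePlant] = ()
    shell_waters: Optional[ShellWaters] = None
    perturbation_sigma: float = 0.0      # thermal jitter, Angstrom; 0 = rigid
    seed: int = 0


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _sphere_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def gen_complex_fixture(spec: ComplexFixtureSpec):
    """Build the fixture and its ground-truth report.

    Returns ``(ensemble, topology, report)``.  The report records, per frame,
    the planted hydrogen bonds, water bridges and in-shell water counts that
    follow from the construction; bridge waters sitting at the bridge site are
    inside the ligand shell and are included in the shell counts.
    """
    nf = spec.n_frames
    if nf < 1:
        raise ValueError("n_frames must be >= 1")

    names, elements, resnames, resids, chains = [], [], [], [], []
    base = []            # per-atom base position (frame-independent part)
    movers = []          # list of (atom_indices, per-frame positions override)
    next_resid = [1]

    def add_atom(name, element, resname, resid, chain, pos):
        names.append(name); elements.append(element); resnames.append(resname)
        resids.append(resid); chains.append(chain)
        base.append(np.asarray(pos, dtype=float))
        return len(names) - 1

    # --- ligand core -------------------------------------------------------
    lig_resid = 900
    lig_center = add_atom("C1", "C", "LIG", lig_resid, "L", (0.0, 0.0, 0.0))

    directions = _sphere_directions(
        max(4, 2 * len(spec.hbond_plants) + 2 * len(spec.bridge_plants) + 4))
    dir_iter = iter(directions)

    report = {"hbonds": {}, "bridges": {}, "shell": None}
    frame_overrides = []   # (atom_index, (n_frames, 3) positions)

    # --- hydrogen-bond plants ---------------------------------------------
    for k, plant in enumerate(spec.hbond_plants):
        present = (np.ones(nf, dtype=bool) if plant.present is None
                   else np.asarray(plant.present, dtype=bool))
        if present.shape != (nf,):
            raise ValueError(f"plant {plant.name!r}: present mask length mismatch")
        d = _unit(next(dir_iter))
        if plant.acceptor_on == "ligand":
            acc_pos = 2.0 * d
            acc = add_atom(f"O{k+1}", "O", "LIG", lig_resid, "L", acc_pos)
        elif plant.acceptor_on == "protein":
            acc_pos = 14.0 * d
            acc = add_atom("O", "O", "ACC", next_resid[0], "A", acc_pos)
            next_resid[0] += 1
        else:
            raise ValueError(f"unknown acceptor_on {plant.acceptor_on!r}")
        don_near = acc_pos + _HB_DA * d
        don_far = acc_pos + _ABSENT_DA * d
        rid = next_resid[0]; next_resid[0] += 1
        don = add_atom("N", "N", "DON", rid, "A", don_near)
        hyd = add_atom("H", "H", "DON", rid, "A", don_near - 1.0 * d)
        don_traj = np.where(present[:, None], don_near[None], don_far[None])
        hyd_traj = don_traj - 1.0 * d
        frame_overrides.append((don, don_traj))
        frame_overrides.append((hyd, hyd_traj))
        report["hbonds"][plant.name] = {
            "donor_index": don, "hydrogen_index": hyd, "acceptor_index": acc,
            "present": present.tolist(),
            "occupancy_pct": 100.0 * present.sum() / nf,
        }

    # --- water bridges -----------------------------------------------------
    bridge_water_atoms = []   # indices of waters that occupy bridge sites
    for k, plant in enumerate(spec.bridge_plants):
        sched = np.asarray(plant.bridging_water, dtype=int)
        if sched.shape != (nf,):
            raise ValueError(f"bridge {plant.name!r}: schedule length mismatch")
        if sched.max(initial=-1) >= plant.n_waters:
            raise ValueError(f"bridge {plant.name!r}: water id out of range")
        d_lig = _unit(next(dir_iter))
        lig_acc_pos = 2.0 * d_lig
        lig_acc = add_atom(f"OB{k+1}", "O", "LIG", lig_resid, "L", lig_acc_pos)
        # water O sits 2.8 A from the ligand acceptor; the protein acceptor
        # sits 2.8 A from the water at the H-O-H angle so both O-H vectors
        # point straight at their acceptors
        u2 = -d_lig                                  # from water toward ligand acceptor
        w_pos = lig_acc_pos + 2.8 * d_lig
        axis = _unit(np.cross(d_lig, [0.0, 0.0, 1.0])
                     if abs(d_lig[2]) < 0.9 else np.cross(d_lig, [1.0, 0.0, 0.0]))
        u1 = math.cos(_WATER_ANGLE) * u2 + math.sin(_WATER_ANGLE) * axis
        prot_acc_pos = w_pos + 2.8 * u1
        prot_acc = add_atom("O", "O", "ACC", next_resid[0], "A", prot_acc_pos)
        next_resid[0] += 1
        water_ids = []
        for wi in range(plant.n_waters):
            rid = next_resid[0]; next_resid[0] += 1
            park = w_pos + _PARK_OFFSET + np.array([8.0 * wi, 8.0 * k, 0.0])
            o = add_atom("OW", "O", "HOH", rid, "W", park)
            h1 = add_atom("HW1", "H", "HOH", rid, "W", park + _WATER_OH * u1)
            h2 = add_atom("HW2", "H", "HOH", rid, "W", park + _WATER_OH * u2)
            on = sched == wi
            o_traj = np.where(on[:, None], w_pos[None], park[None])
            frame_overrides.append((o, o_traj))
            frame_overrides.append((h1, o_traj + _WATER_OH * u1))
            frame_overrides.append((h2, o_traj + _WATER_OH * u2))
            water_ids.append((o, h1, h2))
            bridge_water_atoms.append((o, on))
        bridged = sched >= 0
        persist = (np.bincount(sched[bridged], minlength=plant.n_waters).max()
                   if bridged.any() else 0)
        report["bridges"][plant.name] = {
            "ligand_acceptor_index": lig_acc, "protein_acceptor_index": prot_acc,
            "water_atoms": water_ids,
            "frames_bridged": bridged.tolist(),
            "pair_occupancy_pct": 100.0 * bridged.sum() / nf,
            "max_single_water_persistence_pct": 100.0 * persist / nf,
        }

    # --- shell waters ------------------------------------------------------
    shell_counts = np.zeros(nf, dtype=int)
    for o, on in bridge_water_atoms:
        shell_counts += on.astype(int)
    if spec.shell_waters is not None:
        sw = spec.shell_waters
        n_inside = np.broadcast_to(np.asarray(sw.n_inside, dtype=int), (nf,))
        if n_inside.max(initial=0) > sw.n_total:
            raise ValueError("n_inside exceeds n_total shell waters")
        sdirs = _sphere_directions(max(sw.n_total, 4)) @ np.diag([1, 1, -1])
        for wi in range(sw.n_total):
            dist = (sw.distances[wi] if sw.distances is not None
                    and wi < len(sw.distances) else sw.inside_distance)
            inside_pos = dist * _unit(sdirs[wi] + np.array([0.013, -0.007, 0.019]))
            park = 45.0 * _unit(sdirs[wi]) + np.array([0.0, 0.0, -30.0])
            rid = next_resid[0]; next_resid[0] += 1
            o = add_atom("OW", "O", "HOH", rid, "W", park)
            perp = _unit(np.cross(inside_pos if np.linalg.norm(inside_pos) > 0
                                  else [1, 0, 0], [0.31, 0.64, 0.70]))
            h1d = perp
            h2d = (math.cos(_WATER_ANGLE) * perp
                   + math.sin(_WATER_ANGLE) * _unit(np.cross(perp, sdirs[wi])))
            h1 = add_atom("HW1", "H", "HOH", rid, "W", park + _WATER_OH * h1d)
            h2 = add_atom("HW2", "H", "HOH", rid, "W", park + _WATER_OH * h2d)
            on = wi < n_inside
            o_traj = np.where(on[:, None], inside_pos[None], park[None])
            frame_overrides.append((o, o_traj))
            frame_overrides.append((h1, o_traj + _WATER_OH * h1d))
            frame_overrides.append((h2, o_traj + _WATER_OH * h2d))
            shell_counts += on.astype(int)
        report["shell"] = {
            "planted_inside_per_frame": n_inside.tolist(),
            "counts_per_frame_incl_bridge_waters": shell_counts.tolist(),
        }
    else:
        report["shell"] = {
            "planted_inside_per_frame": [0] * nf,
            "counts_per_frame_incl_bridge_waters": shell_counts.tolist(),
        }

    # --- assemble coordinates ---------------------------------------------
    base_arr = np.array(base)
    coords = np.repeat(base_arr[None, :, :], nf, axis=0)
    for atom, traj in frame_overrides:
        coords[:, atom, :] = traj
    rng = np.random.default_rng(spec.seed)
    if spec.perturbation_sigma > 0:
        coords = coords + spec.perturbation_sigma * rng.standard_normal(coords.shape)

    # overlap sanity check (atoms closer than 0.5 A that are not bonded O-H)
    for f in range(nf):
        tree = cKDTree(coords[f])
        pairs = tree.query_pairs(0.5)
        if pairs:
            i, j = sorted(pairs)[0]
            raise ValueError(
                f"impossible placement: atoms {i} and {j} overlap "
                f"(< 0.5 A) in frame {f}")

    top = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        chainids=np.array(chains, dtype=object))
    times = 0.1 * np.arange(1, nf + 1)
    ens = Ensemble(coords, times, top, f"fixture-seed{spec.seed}")
    return ens, top, report


def write_fixture(ensemble: Ensemble, report: dict, out_dir: str | Path,
                  stem: str = "fixture") -> dict:
    """Write a fixture as PDB + DCD plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb = out / f"{stem}.pdb"
    dcd = out / f"{stem}.dcd"
    js = out / f"{stem}.ground_truth.json"
    write_pdb(ensemble, 0, pdb)
    write_trajectory(ensemble, dcd)
    with open(js, "w") as fh:
        json.dump(report, fh, indent=1)
    return {"pdb": str(pdb), "dcd": str(dcd), "ground_truth": str(js)}
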