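"""Protein-ligand interaction analyses.

Hydrogen bonds and water bridges use a geometric definition: a donor-H ...
acceptor triple counts in a frame when the donor-acceptor distance is within
a cutoff (default 3.5 A) and the D-H-A angle is at least an angular cutoff
(default 135 deg).  All distance cutoffs here use the closed convention
(<=, with a 1e-9 A numerical guard).

SASA is Shrake-Rupley: quasi-uniform points (golden-spiral construction) on
each atom's solvent-expanded sphere (van der Waals radius + probe radius,
probe 1.4 A); the accessible fraction times the sphere area, summed.

The linear interaction energy between a residue and the ligand is the plain
pairwise nonbonded sum over frames:

    E_elec = sum_ij 332.0636 q_i q_j / r_ij          (kcal/mol)
    E_vdw  = sum_ij 4 eps_ij [(sig_ij/r_ij)^12 - (sig_ij/r_ij)^6]

with Lorentz-Berthelot combining (arithmetic sigma, geometric epsilon), no
distance cutoff and unit dielectric; reported as mean +/- SD over frames.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import Ensemble, Selection

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "detect_hbonds",
    "hbond_count_series",
    "water_bridges",
    "sasa",
    "water_shell_count",
    "linear_interaction_energy",
    "VDW_RADII",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 332.0636        # kcal A / (mol e^2)
_EPS = 1e-9                        # closed-boundary numerical guard, Angstrom

# van der Waals radii (A), standard element table
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (donor-acceptor distance, D-H-A angle)."""

    distance_cutoff: float = 3.5       # A, donor-acceptor
    angle_cutoff: float = 135.0        # degrees, at the hydrogen

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.angle_cutoff <= 180.0:
            raise ValueError("angle cutoff must be in (0, 180] degrees")


@dataclass
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    present: np.ndarray            # bool per frame

    @property
    def occupancy_pct(self) -> float:
        return 100.0 * float(np.mean(self.present))


def _attached_hydrogens(ensemble: Ensemble, donors: Sequence[int],
                        max_bond: float = 1.25) -> dict:
    """Hydrogens covalently attached to each donor heavy atom (frame-0 geometry)."""
    top = ensemble.topology
    h_idx = [i for i in range(top.n_atoms) if str(top.elements[i]).upper() == "H"]
    if not h_idx:
        raise ValueError("topology has no hydrogens; hydrogen-bond detection "
                         "needs a hydrogen-bearing topology")
    pos0 = ensemble.coordinates[0]
    tree = cKDTree(pos0[h_idx])
    out = {}
    for d in donors:
        near = tree.query_ball_point(pos0[d], max_bond)
        out[d] = [h_idx[i] for i in near]
    return out


def _hbond_present(coords: np.ndarray, d: int, h: int, a: int,
                   crit: HBondCriteria) -> np.ndarray:
    """Per-frame presence of one D-H...A triple."""
    rda = np.linalg.norm(coords[:, d] - coords[:, a], axis=1)
    v1 = coords[:, d] - coords[:, h]
    v2 = coords[:, a] - coords[:, h]
    cosang = np.einsum("fc,fc->f", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (rda <= crit.distance_cutoff + _EPS) & \
           (ang >= crit.angle_cutoff - 1e-9)


def detect_hbonds(ensemble: Ensemble, donors: Selection, acceptors: Selection,
                  criteria: HBondCriteria = HBondCriteria()) -> list:
    """All donor-H...acceptor triples ever satisfied, with per-frame presence.

    ``donors`` selects donor heavy atoms (their hydrogens are resolved from
    frame-0 geometry); ``acceptors`` selects acceptor heavy atoms.
    """
    h_of = _attached_hydrogens(ensemble, donors.indices)
    missing = [d for d in donors.indices if not h_of[d]]
    if len(missing) == len(donors.indices):
        raise ValueError("no donor has a resolvable attached hydrogen")
    coords = ensemble.coordinates
    records = []
    for d in donors.indices:
        for h in h_of[d]:
            for a in acceptors.indices:
                if a == d or a == h:
                    continue
                present = _hbond_present(coords, d, h, a, criteria)
                if present.any():
                    records.append(HBondRecord(d, h, a, present))
    return records


def hbond_count_series(ensemble: Ensemble, region_a: Selection,
                       region_b: Selection,
                       criteria: HBondCriteria = HBondCriteria(),
                       state_labels: Optional[np.ndarray] = None):
    """Per-frame count of hydrogen bonds between two regions.

    Donor-in-A/acceptor-in-B and donor-in-B/acceptor-in-A triples both
    count.  Donors are the N/O atoms of each region with attached hydrogens;
    acceptors are the N/O atoms of the other region.  Returns
    ``(counts, per_state_means)`` where the second item is a dict (empty when
    no ``state_labels`` are given).
    """
    top = ensemble.topology
    def polar(sel):
        return Selection(tuple(
            i for i in sel.indices
            if str(top.elements[i]).upper() in ("N", "O")), sel.expression)

    counts = np.zeros(ensemble.n_frames)
    for don_region, acc_region in ((region_a, region_b), (region_b, region_a)):
        don, acc = polar(don_region), polar(acc_region)
        if len(don) == 0 or len(acc) == 0:
            continue
        try:
            recs = detect_hbonds(ensemble, don, acc, criteria)
        except ValueError:
            continue
        for r in recs:
            counts += r.present
    means = {}
    if state_labels is not None:
        labels = np.asarray(state_labels)
        for s in np.unique(labels[labels >= 0]):
            means[int(s)] = float(counts[labels == s].mean())
    return counts, means


def water_bridges(ensemble: Ensemble, protein: Selection, ligand: Selection,
                  waters: Selection,
                  criteria: HBondCriteria = HBondCriteria()) -> pd.DataFrame:
    """Water-bridged hydrogen bonds between protein and ligand.

    A bridge exists in a frame when one water simultaneously hydrogen-bonds
    (donor or acceptor role) to a protein atom and to a ligand atom.
    Returns one row per (protein residue, ligand residue) pair with the pair
    occupancy and, separately, the maximum persistence of any single water
    in that bridge — the "conserved water" check: a pair may be bridged in
    every frame while each individual water only bridges briefly.
    """
    top = ensemble.topology
    if len(waters) == 0:
        raise ValueError("empty water selection")
    # group water atoms into molecules by residue
    water_mols: dict = {}
    for i in waters.indices:
        water_mols.setdefault((top.chainids[i], int(top.resids[i])), []).append(i)
    coords = ensemble.coordinates
    nf = ensemble.n_frames

    def polar(indices):
        return [i for i in indices if str(top.elements[i]).upper() in ("N", "O")]

    prot_polar = polar(protein.indices)
    lig_polar = polar(ligand.indices)
    h_all = [i for i in range(top.n_atoms) if str(top.elements[i]).upper() == "H"]
    pos0 = coords[0]
    htree = cKDTree(pos0[h_all]) if h_all else None

    def attached(d):
        if htree is None:
            return []
        return [h_all[k] for k in htree.query_ball_point(pos0[d], 1.25)]

    # presence[(water_res, partner_atom)] computed lazily
    bridges: dict = {}
    for wres, watoms in water_mols.items():
        o_atoms = [i for i in watoms if str(top.elements[i]).upper() == "O"]
        if not o_atoms:
            continue
        wo = o_atoms[0]
        w_h = [i for i in watoms if str(top.elements[i]).upper() == "H"]

        def bonded_to(partner_atoms):
            """Frames in which this water H-bonds any of the partner atoms."""
            out = np.zeros(nf, dtype=bool)
            for a in partner_atoms:
                # water as donor
                for h in w_h:
                    out |= _hbond_present(coords, wo, h, a, criteria)
                # water as acceptor: partner must donate via its hydrogens
                for h in attached(a):
                    out |= _hbond_present(coords, a, h, wo, criteria)
            return out

        to_prot = {}
        for a in prot_polar:
            pres = bonded_to([a])
            if pres.any():
                to_prot[a] = pres
        if not to_prot:
            continue
        to_lig = {}
        for a in lig_polar:
            pres = bonded_to([a])
            if pres.any():
                to_lig[a] = pres
        for pa, ppres in to_prot.items():
            for la, lpres in to_lig.items():
                both = ppres & lpres
                if both.any():
                    key = (top.residue_label(pa), top.residue_label(la))
                    bridges.setdefault(key, {})[wres] = \
                        bridges.setdefault(key, {}).get(wres,
                                                        np.zeros(nf, bool)) | both

    rows = []
    for (pres_label, lig_label), per_water in bridges.items():
        any_frame = np.zeros(nf, dtype=bool)
        max_persist = 0.0
        for pres in per_water.values():
            any_frame |= pres
            max_persist = max(max_persist, float(np.mean(pres)))
        rows.append({
            "protein_residue": pres_label, "ligand_residue": lig_label,
            "pair_occupancy_pct": 100.0 * float(np.mean(any_frame)),
            "max_single_water_persistence_pct": 100.0 * max_persist,
            "n_distinct_waters": len(per_water),
        })
    return pd.DataFrame(rows, columns=[
        "protein_residue", "ligand_residue", "pair_occupancy_pct",
        "max_single_water_persistence_pct", "n_distinct_waters"])


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(ensemble: Ensemble, selection: Selection, probe_radius: float = 1.4,
         n_sphere_points: int = 960, frames: Optional[Sequence[int]] = None):
    """Shrake-Rupley solvent-accessible surface area of a selection (A^2).

    All atoms in the ensemble occlude; only selected atoms contribute area.
    Returns a per-frame array (or a scalar array of length 1 when a single
    frame is requested).
    """
    top = ensemble.topology
    radii = np.empty(top.n_atoms)
    for i in range(top.n_atoms):
        el = str(top.elements[i]).upper()
        if el not in VDW_RADII:
            raise ValueError(f"no van der Waals radius for atom {i} "
                             f"({top.names[i]}, element {el!r})")
        radii[i] = VDW_RADII[el]
    expanded = radii + probe_radius
    pts = _sphere_points(n_sphere_points)
    sel = np.asarray(selection.indices, dtype=int)
    frame_ids = list(range(ensemble.n_frames)) if frames is None else list(frames)
    out = np.empty(len(frame_ids))
    for k, f in enumerate(frame_ids):
        pos = ensemble.coordinates[f]
        tree = cKDTree(pos)
        total = 0.0
        for i in sel:
            ri = expanded[i]
            neighbors = [j for j in tree.query_ball_point(pos[i],
                                                          ri + expanded.max())
                         if j != i]
            neighbors = [j for j in neighbors
                         if np.linalg.norm(pos[j] - pos[i]) < ri + expanded[j]]
            surface = pos[i] + ri * pts
            if neighbors:
                npos = pos[neighbors]
                nrad = expanded[neighbors]
                d2 = ((surface[:, None, :] - npos[None, :, :]) ** 2).sum(-1)
                buried = (d2 < (nrad ** 2)[None, :]).any(axis=1)
                frac = 1.0 - buried.mean()
            else:
                frac = 1.0
            total += frac * 4.0 * math.pi * ri * ri
        out[k] = total
    return out


def water_shell_count(ensemble: Ensemble, ligand: Selection, waters: Selection,
                      radius: float = 5.0) -> np.ndarray:
    """Waters whose O lies within ``radius`` of any ligand atom, per frame.

    The boundary is closed (a water exactly at the radius counts).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    top = ensemble.topology
    o_atoms = [i for i in waters.indices if str(top.elements[i]).upper() == "O"]
    lig = list(ligand.indices)
    counts = np.zeros(ensemble.n_frames, dtype=int)
    for f in range(ensemble.n_frames):
        pos = ensemble.coordinates[f]
        ltree = cKDTree(pos[lig])
        d, _ = ltree.query(pos[o_atoms], k=1)
        counts[f] = int(np.sum(d <= radius + _EPS))
    return counts


# ---------------------------------------------------------------------------
# linear interaction energy
# ---------------------------------------------------------------------------

def linear_interaction_energy(ensemble: Ensemble, params: pd.DataFrame,
                              residue: Selection, ligand: Selection,
                              clash_distance: float = 0.5) -> dict:
    """Pairwise Coulomb + Lennard-Jones energy between a residue and the ligand.

    ``params`` is indexed by atom index with columns ``charge`` (e),
    ``sigma`` (A) and ``epsilon`` (kcal/mol).  Lorentz-Berthelot combining;
    no cutoff; dielectric 1.  Returns a dict with per-frame arrays and
    mean/SD for the electrostatic and van der Waals terms; frames containing
    a pair closer than ``clash_distance`` are flagged.
    """
    ri = np.asarray(residue.indices, dtype=int)
    li = np.asarray(ligand.indices, dtype=int)
    needed = set(ri.tolist()) | set(li.tolist())
    missing = needed - set(int(i) for i in params.index)
    if missing:
        raise ValueError(f"missing parameters for atoms {sorted(missing)[:5]}")
    q = params["charge"]
    sg = params["sigma"]
    ep = params["epsilon"]
    qi, qj = q.loc[ri].values, q.loc[li].values
    si, sj = sg.loc[ri].values, sg.loc[li].values
    ei, ej = ep.loc[ri].values, ep.loc[li].values
    qq = COULOMB_CONSTANT * np.outer(qi, qj)
    sig = 0.5 * (si[:, None] + sj[None, :])
    eps = np.sqrt(np.outer(ei, ej))
    a = ensemble.coordinates[:, ri, :]
    b = ensemble.coordinates[:, li, :]
    diff = a[:, :, None, :] - b[:, None, :, :]
    r = np.sqrt((diff ** 2).sum(-1))
    clash = (r < clash_distance).any(axis=(1, 2))
    if clash.any():
        warnings.warn(f"{int(clash.sum())} frames contain atom pairs closer "
                      f"than {clash_distance} A (clash)")
    elec = (qq[None] / r).sum(axis=(1, 2))
    sr6 = (sig[None] / r) ** 6
    vdw = (4.0 * eps[None] * (sr6 ** 2 - sr6)).sum(axis=(1, 2))
    return {
        "electrostatic": elec,
        "vdw": vdw,
        "electrostatic_mean": float(elec.mean()),
        "electrostatic_sd": float(elec.std(ddof=0)),
        "vdw_mean": float(vdw.mean()),
        "vdw_sd": float(vdw.std(ddof=0)),
        "clash_frames": np.where(clash)[0].tolist(),
    }
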