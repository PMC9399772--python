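"""Two-system comparative analysis pipeline.

One configuration (YAML/JSON or a :class:`RunConfig`) describes two systems
— each either topology + trajectory files or a synthetic Gaussian ensemble —
plus selections and per-stage parameters.  :func:`run_compare` then executes
the stages in order: superposition, RMSD/RMSF and the per-residue RMSF
difference, distance collective variables, PCA, free-energy landscapes, a
Markov state model (implied timescales, macrostates, representative frames),
correlation matrices, the dynamic network with communities and an optimal
path, and (when the system carries a ligand and waters) interaction
analyses.

A failing stage is logged and does not abort the remaining stages; all
randomness derives from the configured seed, so a rerun reproduces the
report bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import metrics, msm as msm_mod, network as net_mod
from .io import Ensemble, Selection, load_topology, load_trajectory, select, write_pdb
from .synthetic import GaussianEnsembleSpec, gen_gaussian_ensemble

__all__ = ["SystemConfig", "RunConfig", "ComparisonReport", "run_compare",
           "load_config"]


@dataclass
class SystemConfig:
    label: str
    topology: Optional[str] = None
    trajectories: tuple = ()
    frame_time_step: float = 1.0          # ns per frame
    synthetic: Optional[dict] = None      # GaussianEnsembleSpec kwargs

    def load(self, seed: int) -> Ensemble:
        if self.synthetic is not None:
            kwargs = dict(self.synthetic)
            kwargs.setdefault("seed", seed)
            ens = gen_gaussian_ensemble(GaussianEnsembleSpec(**kwargs))
            ens.system_label = self.label
            return ens
        if not self.topology or not self.trajectories:
            raise ValueError(f"system {self.label!r}: need topology + "
                             "trajectories or a synthetic spec")
        top = load_topology(self.topology)
        ens = load_trajectory(top, list(self.trajectories), self.frame_time_step)
        ens.system_label = self.label
        return ens


@dataclass
class RunConfig:
    systems: tuple                        # two SystemConfig for compare mode
    output_dir: str = "dynalysis_run"
    seed: int = 0
    fit_selection: str = "name CA"
    cv_pairs: tuple = ()                  # ((expr_i, expr_j), (expr_i, expr_j))
    landscape_bins: int = 40
    temperature_K: float = 300.0
    msm_params: dict = field(default_factory=lambda: {
        "n_microstates": 100, "lag_frames": 1, "n_macrostates": 2})
    network_params: dict = field(default_factory=lambda: {
        "contact_cutoff": 4.5, "occupancy": 0.75})
    path_endpoints: Optional[tuple] = None   # (source_label, target_label)
    run_gc: bool = False
    gc_max_frames: int = 5000
    interaction_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.systems) != 2:
            raise ValueError("compare mode requires exactly two systems")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    systems = tuple(SystemConfig(**s) for s in raw.pop("systems"))
    return RunConfig(systems=systems, **raw)


@dataclass
class ComparisonReport:
    config_hash: str
    seed: int
    results: dict
    errors: dict

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"config_hash": self.config_hash, "seed": self.seed,
                    "errors": self.errors,
                    "stages": sorted(self.results.keys())}
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=1)
        return path


def _hash_config(cfg: RunConfig) -> str:
    blob = repr(cfg).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_compare(config: RunConfig) -> ComparisonReport:
    """Execute the full comparative pipeline; see the module docstring."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    errors: dict = {}

    def stage(name):
        def deco(fn):
            try:
                results[name] = fn()
            except Exception as exc:
                errors[name] = f"{type(exc).__name__}: {exc}"
                results[name] = None
            return None
        return deco

    ensembles = []
    for k, sc in enumerate(config.systems):
        ensembles.append(sc.load(seed=config.seed + k))
    labels = [e.system_label for e in ensembles]

    fits = [select(e.topology, config.fit_selection) for e in ensembles]

    @stage("superpose")
    def _superpose():
        sup = []
        for e, s in zip(ensembles, fits):
            sup.append(metrics.superpose(e, s) if len(s) >= 3 else e)
        ensembles[:] = sup
        return {"applied": [len(s) >= 3 for s in fits]}

    @stage("rmsd")
    def _rmsd():
        res = {}
        for e, s in zip(ensembles, fits):
            series = metrics.rmsd_series(e, s, reference=0)
            res[e.system_label] = {"mean": series.mean, "sd": series.std}
            pd.DataFrame({"time_ns": e.frame_times,
                          "rmsd_A": series.values}).to_csv(
                out / f"rmsd_{e.system_label}.csv", index=False)
        return res

    rmsf_tables = {}

    @stage("rmsf")
    def _rmsf():
        for e, s in zip(ensembles, fits):
            tab = metrics.rmsf(e, s)
            rmsf_tables[e.system_label] = tab
            tab.to_csv(out / f"rmsf_{e.system_label}.csv", index=False)
        delta = metrics.rmsf_difference(rmsf_tables[labels[0]],
                                        rmsf_tables[labels[1]])
        delta.to_csv(out / "delta_rmsf.csv", index=False)
        return {"delta_convention": f"{labels[0]} - {labels[1]}",
                "delta": delta}

    cv_store: dict = {}

    @stage("distance_cvs")
    def _cvs():
        if not config.cv_pairs:
            return {}
        res = {}
        for e in ensembles:
            pair_series = []
            for expr_i, expr_j in config.cv_pairs:
                si = select(e.topology, expr_i)
                sj = select(e.topology, expr_j)
                name = f"d({expr_i})-({expr_j})"
                mode = "atom" if len(si) == 1 and len(sj) == 1 else "centroid"
                pair_series.append(
                    metrics.distance_series(e, si, sj, mode=mode, name=name))
            cv_store[e.system_label] = pair_series
            res[e.system_label] = [s.summary() for s in pair_series]
        return res

    @stage("pca")
    def _pca():
        res = {}
        for e, s in zip(ensembles, fits):
            p = metrics.pca(e, s, n_modes=10)
            res[e.system_label] = {
                "eigenvalues": p.eigenvalues.tolist(),
                "explained_pc1_pc2": p.explained_variance_ratio()[:2].tolist(),
            }
            np.savetxt(out / f"pca_projections_{e.system_label}.csv",
                       p.projections[:, :2], delimiter=",",
                       header="pc1,pc2", comments="")
            if e.system_label not in cv_store:
                cv_store[e.system_label] = [
                    metrics.ScalarSeries("PC1", p.projections[:, 0], "A"),
                    metrics.ScalarSeries("PC2", p.projections[:, 1], "A")]
        return res

    @stage("landscape")
    def _landscape():
        res = {}
        for e in ensembles:
            cvs = cv_store.get(e.system_label)
            if not cvs or len(cvs) < 2:
                continue
            land = metrics.free_energy_landscape(
                cvs[0], cvs[1], bins=config.landscape_bins,
                temperature_K=config.temperature_K)
            np.savetxt(out / f"landscape_{e.system_label}.csv",
                       land.free_energy_kt, delimiter=",")
            occ = np.isfinite(land.free_energy_kt)
            res[e.system_label] = {
                "occupied_bins": int(occ.sum()),
                "max_kt": float(np.nanmax(land.free_energy_kt)),
            }
        return res

    @stage("msm")
    def _msm():
        res = {}
        mp = config.msm_params
        for e in ensembles:
            cvs = cv_store.get(e.system_label)
            if not cvs or len(cvs) < 2:
                continue
            pts = np.column_stack([cvs[0].values, cvs[1].values])
            k = min(mp.get("n_microstates", 100),
                    len(np.unique(pts, axis=0)))
            micro = msm_mod.cluster_microstates(pts, k=k, seed=config.seed)
            lag = mp.get("lag_frames", 1)
            lags = [l for l in (1, 2, 3, 5, 8, 10) if l < e.n_frames]
            its = msm_mod.implied_timescales(
                micro.assignments, lags,
                frame_time=float(np.diff(e.frame_times).mean()),
                n_timescales=3)
            its.to_csv(out / f"its_{e.system_label}.csv", index=False)
            tm = msm_mod.estimate_transitions(
                micro.assignments, lag,
                frame_time=float(np.diff(e.frame_times).mean()))
            n_macro = min(mp.get("n_macrostates", 2),
                          len(tm.active_states))
            part = msm_mod.coarse_grain(tm, n_macro)
            state_of_micro = {int(s): int(m) for s, m in
                              zip(part.active_states, part.memberships)}
            frame_macro = np.array([state_of_micro.get(int(a), -1)
                                    for a in micro.assignments])
            reps = {}
            sel = select(e.topology, config.fit_selection)
            for m in range(n_macro):
                try:
                    fidx = msm_mod.representative_structure(
                        e, frame_macro, m, sel, max_frames=200,
                        seed=config.seed)
                    pdb = out / f"representative_{e.system_label}_state{m}.pdb"
                    write_pdb(e, fidx, pdb)
                    reps[m] = {"frame": int(fidx), "pdb": str(pdb)}
                except ValueError:
                    reps[m] = {"frame": None}
            res[e.system_label] = {
                "n_microstates": k,
                "macrostate_populations": part.populations.tolist(),
                "representatives": reps,
            }
        return res

    corr_store: dict = {}

    @stage("dccm")
    def _dccm():
        res = {}
        for e, s in zip(ensembles, fits):
            C = net_mod.dccm(e, s)
            corr_store[e.system_label] = C
            C.to_dataframe().to_csv(out / f"dccm_{e.system_label}.csv")
            res[e.system_label] = {"mean_abs_offdiag": float(
                np.nanmean(np.abs(C.values[~np.eye(len(C.values), dtype=bool)])))}
        return res

    @stage("generalized_correlation")
    def _gc():
        if not config.run_gc:
            return {"skipped": True}
        res = {}
        for e, s in zip(ensembles, fits):
            G = net_mod.generalized_correlation(
                e, s, max_frames=config.gc_max_frames)
            G.to_dataframe().to_csv(out / f"gc_{e.system_label}.csv")
            res[e.system_label] = {"mean_offdiag": float(
                np.mean(G.values[~np.eye(len(G.values), dtype=bool)]))}
        return res

    @stage("network")
    def _network():
        import networkx as nx
        res = {}
        np_ = config.network_params
        for e, s in zip(ensembles, fits):
            C = corr_store.get(e.system_label)
            if C is None:
                continue
            g = net_mod.build_network(e, C, s, **np_)
            nx.write_graphml(g, out / f"network_{e.system_label}.graphml")
            part = net_mod.communities(g) if g.number_of_nodes() else None
            entry = {"n_edges": g.number_of_edges(),
                     "n_communities": len(part.sizes) if part else 0,
                     "modularity": part.modularity if part else None}
            if config.path_endpoints:
                src, tgt = config.path_endpoints
                if src in g and tgt in g:
                    path, w = net_mod.optimal_path(g, src, tgt)
                    entry["optimal_path"] = path
                    entry["path_weight"] = w
                    entry["path_length_A"] = net_mod.path_physical_length(g, path)
            res[e.system_label] = entry
        return res

    @stage("interactions")
    def _interactions():
        ip = config.interaction_params
        if not ip:
            return {"skipped": True}
        from . import interactions as ia
        from .io import load_atom_parameters
        res = {}
        crit = ia.HBondCriteria(ip.get("hbond_distance", 3.5),
                                ip.get("hbond_angle", 135.0))
        for e in ensembles:
            entry = {}
            lig = select(e.topology, ip["ligand"]) if "ligand" in ip else None
            wat = select(e.topology, ip["waters"]) if "waters" in ip else None
            prot = select(e.topology, ip["protein"]) if "protein" in ip else None
            if "region_a" in ip and "region_b" in ip:
                ra = select(e.topology, ip["region_a"])
                rb = select(e.topology, ip["region_b"])
                counts, _ = ia.hbond_count_series(e, ra, rb, crit)
                entry["hbond_count_mean"] = float(counts.mean())
            if lig is not None and wat is not None and prot is not None:
                wb = ia.water_bridges(e, prot, lig, wat, crit)
                wb.to_csv(out / f"water_bridges_{e.system_label}.csv",
                          index=False)
                entry["n_bridge_pairs"] = len(wb)
            if lig is not None:
                area = ia.sasa(e, lig,
                               n_sphere_points=ip.get("sasa_points", 960))
                entry["sasa_mean_A2"] = float(area.mean())
                if wat is not None:
                    sc = ia.water_shell_count(
                        e, lig, wat, radius=ip.get("shell_radius", 5.0))
                    entry["shell_count_mean"] = float(sc.mean())
            if lig is not None and "atom_parameters" in ip and "residue" in ip:
                par = load_atom_parameters(ip["atom_parameters"])
                resi = select(e.topology, ip["residue"])
                lie = ia.linear_interaction_energy(e, par, resi, lig)
                entry["lie"] = {k: lie[k] for k in
                                ("electrostatic_mean", "electrostatic_sd",
                                 "vdw_mean", "vdw_sd")}
            res[e.system_label] = entry
        return res

    report = ComparisonReport(_hash_config(config), config.seed, results, errors)
    report.save(out)
    return report
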