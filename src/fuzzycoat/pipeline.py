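"""Config-driven orchestration of the full toy workflow:

    synth → map/GMM → metainference → metadynamics reweighting → structural
    analyses → solvent diffusion → report

Each stage writes tidy tabular outputs into the output directory, stamped
with a hash of the resolved configuration; a manifest records inputs,
parameters, seeds, versions and per-stage wall times. The default
configuration doubles as the ``--demo`` preset and runs end-to-end in a few
minutes on one CPU.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_CONFIG = {
    "seed": 1,
    "output_dir": "fuzzycoat_out",
    "stages": {"synth": True, "maps": True, "metainference": True,
               "metadynamics": True, "analysis": True, "solvent": True},
    "filament": {
        "n_chains_per_protofilament": 4,
        "n_protofilaments": 1,
        "core_range": [5, 14],
        "tail_range": [1, 4],
        "sequence": "DAEFLVFFAEDVGS",
        "axial_rise": 0.48,
        "tail_flexibility": 0.5,
    },
    "ensemble": {"n_frames": 30},
    "map": {"voxel_size": 0.15, "resolution_sigma": 0.15, "noise_sd": 0.0,
            "segment_cutoff": 0.6, "gmm_components": 12},
    "metainference": {"n_replicas": 4, "n_steps": 150, "move_deg": 12.0,
                      "mixture": [0.7, 0.3]},
    "metadynamics": {"n_steps": 30000, "hill_height": 0.5, "hill_width": 0.15,
                     "gamma": 10.0, "deposit_stride": 100, "n_bins": 40,
                     "block_sizes": [10, 100, 1000],
                     "well_a": 4.0, "well_c": 1.0},
    "analysis": {"contact_cutoff": 1.0, "probe": 0.34, "sasa_points": 192,
                 "n_solubility_conformations": 10},
    "solvent": {"n_particles": 200, "n_steps": 2000, "dt": 1.0,
                "d_true": 0.0023, "cyl_radius": 1.0, "cyl_height": 3.6},
}


def validate_config(config: dict, defaults: dict = None, path: str = "") -> dict:
    """Merge over the defaults, rejecting unknown keys by name."""
    if defaults is None:
        defaults = DEFAULT_CONFIG
    out = copy.deepcopy(defaults)
    for key, value in (config or {}).items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{path + key!r} must be a mapping")
            out[key] = validate_config(value, defaults[key], path + key + ".")
        else:
            out[key] = value
    return out


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_table(df, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: dict | None = None, demo: bool = False) -> dict:
    """Execute the enabled stages in order; returns a summary dict (also
    written as manifest.json). Stage failures raise :class:`StageError`
    naming the stage; outputs of completed stages are retained."""
    import pandas as pd

    from . import analysis, maps, metad, metainference as mi, solvent, synth

    cfg = validate_config({} if demo else (config or {}))
    chash = config_hash(cfg)
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"config": cfg, "config_hash": chash, "seed": seed,
                "stages": {}, "summary": {}}
    ctx = {}

    stage_order = ["synth", "maps", "metainference", "metadynamics",
                   "analysis", "solvent"]
    runners = {"synth": _stage_synth, "maps": _stage_maps,
               "metainference": _stage_metainference,
               "metadynamics": _stage_metadynamics,
               "analysis": _stage_analysis, "solvent": _stage_solvent}
    for name in stage_order:
        if not cfg["stages"].get(name, False):
            continue
        t0 = time.time()
        logger.info("stage %s starting", name)
        try:
            runners[name](cfg, seed, out_dir, chash, ctx, manifest)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(out_dir, manifest)
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.time() - t0, 2)}
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
    _write_manifest(out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)


def _stage_synth(cfg, seed, out_dir, chash, ctx, manifest):
    from . import model as M, synth

    f = cfg["filament"]
    spec = synth.ToyFilamentSpec(
        n_chains_per_protofilament=int(f["n_chains_per_protofilament"]),
        n_protofilaments=int(f["n_protofilaments"]),
        core_range=tuple(f["core_range"]), tail_range=tuple(f["tail_range"]),
        sequence=f["sequence"], axial_rise=float(f["axial_rise"]),
        tail_flexibility=float(f["tail_flexibility"]), seed=seed)
    filament = synth.build_toy_filament(spec)
    ens = synth.sample_tail_ensemble(filament, int(cfg["ensemble"]["n_frames"]),
                                     seed=seed + 1)
    M.write_pdb(out_dir / "filament.pdb", filament)
    M.write_pdb(out_dir / "ensemble.pdb", ens)
    n_ions, sign = synth.counterions_to_neutralize(f["sequence"], spec.n_chains)
    manifest["summary"]["counterions"] = {"count": n_ions, "sign": sign}
    ctx.update(spec=spec, filament=filament, ensemble=ens)


def _stage_maps(cfg, seed, out_dir, chash, ctx, manifest):
    import pandas as pd

    from . import maps, synth

    m = cfg["map"]
    ens = ctx["ensemble"]
    data_map = synth.render_synthetic_map(ens, float(m["voxel_size"]),
                                          float(m["resolution_sigma"]),
                                          noise_sd=float(m["noise_sd"]), seed=seed)
    trimmed = maps.segment_map(data_map, ctx["filament"], float(m["segment_cutoff"]))
    fit = maps.fit_gmm(trimmed, int(m["gmm_components"]), seed=seed)
    rendered = maps.render_map_from_gmm(fit.mixture, like=trimmed)
    fsc = maps.fourier_shell_correlation(rendered, trimmed)
    maps.save_mrc(out_dir / "data_map.mrc", data_map)
    maps.save_mrc(out_dir / "trimmed_map.mrc", trimmed)
    maps.save_gmm(out_dir / "data_gmm.txt", fit.mixture,
                  metadata={"config_hash": chash, "correlation": fit.correlation})
    _write_table(pd.DataFrame({"frequency_inv_nm": fsc.frequencies,
                               "fsc": fsc.correlation, "count": fsc.counts}),
                 out_dir / "fsc.csv", chash)
    manifest["summary"]["gmm_fit_correlation"] = fit.correlation
    ctx.update(data_map=data_map, trimmed_map=trimmed, data_gmm=fit.mixture)


def _stage_metainference(cfg, seed, out_dir, chash, ctx, manifest):
    import pandas as pd

    from . import metainference as mi, model as M, synth
    from .maps import (GaussianMixture, grid_for_support, real_space_correlation,
                       render_map_from_gmm)

    mc = cfg["metainference"]
    model = ctx["filament"]
    spec = ctx["spec"]
    chains = [model.chains[(len(model.chains) + 1) // 2 - 1]]
    n_tail = len(spec.tail_residues)
    conf_a = np.tile([-60.0, -40.0], (n_tail, 1))[None]
    conf_b = np.tile([-150.0, 150.0], (n_tail, 1))[None]
    mask = synth.tail_atom_mask(model, spec, chains[0]) & (model.elements != "H")

    def coords_for(tors):
        c = model.coords.copy()
        mm = synth.tail_atom_mask(model, spec, chains[0])
        c[mm] = synth.tail_coords_from_torsions(model, chains[0], tors[0])
        return c

    ca, cb = coords_for(conf_a), coords_for(conf_b)
    wa, wb = cfg["metainference"]["mixture"]
    ga = mi.model_to_gmm(model.with_coords(ca).select(mask))
    gb = mi.model_to_gmm(model.with_coords(cb).select(mask))
    data = GaussianMixture.concatenate([ga.scaled(wa), gb.scaled(wb)])
    res = mi.run_toy_metainference(
        None, data, int(mc["n_replicas"]), int(mc["n_steps"]), model,
        seed=seed, chains=chains, move_deg=float(mc["move_deg"]),
        reference_conformers=np.concatenate([conf_a[None], conf_b[None]]),
        reflect_prob=0.25, sigma_b_frac=0.2)
    labels = mi.assign_to_references(res.ensemble, [ca, cb], mask)
    grid = grid_for_support(data, 0.1)
    data_map = render_map_from_gmm(data, like=grid)
    post_gmm = GaussianMixture.concatenate(
        [mi.model_to_gmm(res.ensemble.frame(i).select(mask)).scaled(
            1.0 / res.ensemble.n_frames) for i in range(res.ensemble.n_frames)])
    cc_post = real_space_correlation(render_map_from_gmm(post_gmm, like=grid), data_map)
    M.write_pdb(out_dir / "posterior_ensemble.pdb", res.ensemble)
    trace = pd.DataFrame({
        "restraint": [e.restraint for e in res.energy_trace],
        "error": [e.error for e in res.energy_trace],
        "total": [e.total for e in res.energy_trace]})
    _write_table(trace, out_dir / "metainference_energy_trace.csv", chash)
    state = res.state
    rel = mi.relative_error_per_gaussian(state, sigma_samples=res.sigma_trace)
    _write_table(pd.DataFrame({"component": np.arange(len(rel)),
                               "relative_error": rel}),
                 out_dir / "relative_error.csv", chash)
    manifest["summary"]["metainference"] = {
        "posterior_fraction_a": float(np.mean(labels == 0)),
        "target_fraction_a": float(wa),
        "map_correlation_posterior": cc_post,
        "acceptance": res.acceptance,
        "mean_relative_error": float(np.mean(rel)),
    }
    ctx.update(metainference_result=res)


def _stage_metadynamics(cfg, seed, out_dir, chash, ctx, manifest):
    import pandas as pd
    from scipy.integrate import quad

    from . import metad

    md = cfg["metadynamics"]
    a, c = float(md["well_a"]), float(md["well_c"])

    def energy(x):
        return a * (x * x - 1.0) ** 2 + c * x

    bias = metad.BiasState(n_cvs=1, gamma=float(md["gamma"]), kBT=1.0)
    trace, bias = metad.run_biased_mc_1d(
        energy, x0=-1.0, step_sd=0.2, n_steps=int(md["n_steps"]), bias=bias,
        deposit_stride=int(md["deposit_stride"]),
        hill_height=float(md["hill_height"]), hill_width=float(md["hill_width"]),
        seed=seed)
    burn = len(trace) // 5
    tr = trace[burn:]
    w = metad.unbias_weights(bias, tr[:, None])
    centers, fes = metad.free_energy_profile(tr, w, int(md["n_bins"]))
    blocks = metad.block_average_error(tr, [b for b in md["block_sizes"]
                                            if 2 * b <= len(tr)])
    zl = quad(lambda x: np.exp(-energy(x)), -3, 0)[0]
    zr = quad(lambda x: np.exp(-energy(x)), 0, 3)[0]
    df_true = -np.log(zr / zl)
    df_est = -np.log(w[tr > 0].sum() / w[tr < 0].sum())
    _write_table(bias.hills_table(), out_dir / "hills.csv", chash)
    _write_table(pd.DataFrame({"cv": centers, "free_energy_kBT": fes}),
                 out_dir / "free_energy_profile.csv", chash)
    _write_table(pd.DataFrame({"block_size": list(blocks),
                               "block_se": list(blocks.values())}),
                 out_dir / "block_errors.csv", chash)
    manifest["summary"]["metadynamics"] = {
        "delta_f_estimate_kBT": float(df_est),
        "delta_f_analytic_kBT": float(df_true),
        "abs_error_kBT": float(abs(df_est - df_true))}


def _stage_analysis(cfg, seed, out_dir, chash, ctx, manifest):
    import pandas as pd

    from . import analysis

    an_cfg = cfg["analysis"]
    ens = ctx["ensemble"]
    spec = ctx["spec"]
    cmap = analysis.contact_map(ens, cutoff=float(an_cfg["contact_cutoff"]))
    _write_table(cmap.to_frame(), out_dir / "contact_map.csv", chash)
    shielding = analysis.sasa_shielding(
        ens, spec.tail_residues, probe=float(an_cfg["probe"]),
        n_points=int(an_cfg["sasa_points"]))
    _write_table(pd.DataFrame(
        [{"chain": r[0], "res_index": r[1], "delta_sasa_nm2": v}
         for r, v in shielding.items()]), out_dir / "sasa_shielding.csv", chash)
    ss = analysis.assign_secondary_structure(ens)
    _write_table(pd.DataFrame(
        [{"chain": r[0], "res_index": r[1], **v} for r, v in ss.items()]),
        out_dir / "secondary_structure.csv", chash)
    sol = analysis.aggregate_solubility(
        ens, n_conformations=min(int(an_cfg["n_solubility_conformations"]),
                                 ens.n_frames), seed=seed)
    manifest["summary"]["solubility"] = {
        "core_with_coat": [sol.core_mean_with, sol.core_sd_with],
        "core_without_coat": [sol.core_mean_without, sol.core_sd_without]}
    _write_table(pd.DataFrame(
        [{"chain": r[0], "res_index": r[1],
          "score_with_mean": sol.per_residue_with[r][0],
          "score_with_sd": sol.per_residue_with[r][1],
          "score_without_mean": sol.per_residue_without[r][0],
          "score_without_sd": sol.per_residue_without[r][1]}
         for r in sol.per_residue_with]), out_dir / "solubility.csv", chash)


def _stage_solvent(cfg, seed, out_dir, chash, ctx, manifest):
    import pandas as pd

    from . import solvent, synth

    sv = cfg["solvent"]
    region = solvent.CylinderRegion(radius=float(sv["cyl_radius"]),
                                    height=float(sv["cyl_height"]),
                                    center=np.zeros(3))
    rows = []
    for label, confined in (("free", None), ("groove", region)):
        trajs = [synth.simulate_brownian(
            int(sv["n_particles"]), float(sv["d_true"]), float(sv["dt"]),
            int(sv["n_steps"]), confinement=confined, seed=seed + 10 * k)
            for k in range(3)]
        msd = solvent.mean_square_displacement(
            trajs, region=None if confined is None else region, origin_stride=20)
        msd = solvent.diffusion_coefficient(msd)
        rows.append({"selection": label, "diffusion_nm2_per_ps": msd.diffusion,
                     "diffusion_err": msd.diffusion_err,
                     "d_true": float(sv["d_true"]),
                     "n_particles": int(sv["n_particles"])})
        _write_table(pd.DataFrame({"lag_ps": msd.lag_times, "msd_nm2": msd.msd,
                                   "msd_sd": msd.msd_sd}),
                     out_dir / f"msd_{label}.csv", chash)
    _write_table(pd.DataFrame(rows), out_dir / "diffusion.csv", chash)
    manifest["summary"]["diffusion"] = {r["selection"]: r["diffusion_nm2_per_ps"]
                                        for r in rows}
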