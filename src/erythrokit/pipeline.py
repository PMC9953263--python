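"""End-to-end pipeline driven by one structured config.

A config (YAML file or plain dict) names the stages to run, a global seed,
and per-stage parameters; all file paths are resolved relative to the config
file.  Stages::

    simulate   generate populations, OFT recordings, velocity datasets,
               spectra, volumes and cytometry event tables per group
    oft        osmotic-resistance statistics per recording
    micro      velocity PDFs, slow/fast fractions, occlusion rates
    spectro    free hemoglobin and species fractions
    hemocyto   hematology summary, MFI normalization, gated fractions
    compare    group-comparison statistics on a (group, value) table

Unknown stages and missing input files are rejected before any computation.
Results are JSON written deterministically, so a fixed seed reproduces the
output byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, hemocyto, io, micro, oft, stats
from .errors import ConfigurationError
from .spectro import hb_species_fractions, free_hb_percent
from .synth.cyto import CytometrySpec, simulate_cytometry_events
from .synth.micro import simulate_velocity_dataset
from .synth.oft import simulate_oft_recording
from .synth.population import preset_population, sample_population
from .synth.spectra import simulate_absorbance

log = logging.getLogger(__name__)

STAGES = ("simulate", "oft", "micro", "spectro", "hemocyto", "compare")
DEFAULT_STAGES = ("simulate", "oft", "micro", "spectro", "hemocyto")

# supernatant heme concentration (mM) per group: treated cells release more
# free hemoglobin into the medium than control
_SUPERNATANT_HB = {
    "Control": 0.005, "TAX": 0.05, "PLAT": 0.012, "TAX_PLAT": 0.055,
    "RUBI": 0.025, "PHOS": 0.015, "RUBI_PHOS": 0.03,
}
_LYSATE_HB = 0.5


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    config["_base_dir"] = path.parent
    return config


def _resolve(config: dict, p) -> Path:
    base = Path(config.get("_base_dir", "."))
    p = Path(p)
    return p if p.is_absolute() else base / p


def _collect_paths(config: dict) -> list:
    """Every file path a configured stage will read."""
    paths = []
    for stage in ("oft", "micro", "spectro", "hemocyto", "compare"):
        block = config.get(stage) or {}
        for key in ("recordings", "velocities", "volumes"):
            val = block.get(key)
            if isinstance(val, dict):
                for v in val.values():
                    paths.extend(v if isinstance(v, list) else [v])
            elif isinstance(val, list):
                paths.extend(val)
            elif isinstance(val, str):
                paths.append(val)
        for key in ("supernatant", "lysate", "data", "stained", "unstained"):
            if isinstance(block.get(key), str):
                paths.append(block[key])
    return paths


def _validate(config: dict) -> list[str]:
    stages = list(config.get("stages", DEFAULT_STAGES))
    for s in stages:
        if s not in STAGES:
            raise ConfigurationError(f"unknown pipeline stage {s!r}; expected one of {STAGES}")
    for p in _collect_paths(config):
        rp = _resolve(config, p)
        if not rp.exists():
            raise ConfigurationError(f"configured input file does not exist: {rp}")
    return stages


def _stage_simulate(config, ctx, outdir, rng_seeds):
    block = config.get("simulate") or {}
    groups = block.get("groups", ["Control", "TAX"])
    n_cells = int(block.get("n_cells", 2000))
    n_experiments = int(block.get("n_experiments", 3))
    noise_rel = float(block.get("noise_rel", 0.01))
    written = {}
    for gi, group in enumerate(groups):
        seed = rng_seeds[f"simulate/{group}"]
        spec = preset_population(group, n_cells=n_cells, seed=seed)
        cells = sample_population(spec)
        pop_path = outdir / f"population_{group}.csv"
        cells.to_frame().to_csv(pop_path, index=False)

        rec = simulate_oft_recording(cells, noise_rel=noise_rel, seed=seed + 1)
        rec_path = outdir / f"oft_{group}.csv"
        io.write_recording_csv(rec, rec_path)

        vel_paths = []
        datasets = []
        for k in range(n_experiments):
            ds = simulate_velocity_dataset(spec, seed=seed + 10 + k)
            vp = outdir / f"velocities_{group}_{k}.csv"
            cp = outdir / f"channels_{group}_{k}.csv"
            io.write_velocity_dataset(ds, vp, cp)
            vel_paths.append(vp)
            datasets.append(ds)

        sup = simulate_absorbance(
            (1.0, 0.0, 0.0), total_hb=_SUPERNATANT_HB.get(group, 0.02),
            noise_sd=0.002, seed=seed + 30, dilution_factor=20.0,
        )
        lys = simulate_absorbance(
            (0.92, 0.05, 0.03), total_hb=_LYSATE_HB,
            noise_sd=0.002, seed=seed + 31, dilution_factor=200.0, role="whole_lysate",
        )
        sup_path = outdir / f"supernatant_{group}.csv"
        lys_path = outdir / f"lysate_{group}.csv"
        io.write_spectrum_csv(sup, sup_path)
        io.write_spectrum_csv(lys, lys_path)

        stained = simulate_cytometry_events(
            CytometrySpec(label=group, seed=seed + 40, positive_fraction=0.02 * (gi + 1))
        )
        unstained = simulate_cytometry_events(
            CytometrySpec(label=group, stained=False, seed=seed + 41)
        )
        st_path = outdir / f"events_stained_{group}.csv"
        un_path = outdir / f"events_unstained_{group}.csv"
        stained.to_csv(st_path, index=False)
        unstained.to_csv(un_path, index=False)

        ctx.setdefault("recordings", {})[group] = rec
        ctx.setdefault("cells", {})[group] = cells
        ctx.setdefault("velocity_datasets", {})[group] = datasets
        ctx.setdefault("spectra", {})[group] = (sup, lys)
        ctx.setdefault("events", {})[group] = (stained, unstained)
        written[group] = {
            "population": str(pop_path),
            "recording": str(rec_path),
            "velocities": [str(p) for p in vel_paths],
            "supernatant": str(sup_path),
            "lysate": str(lys_path),
        }
    io.write_results_json({"groups": groups, "files": written}, outdir / "simulate_manifest.json")
    return {"groups": groups}


def _stage_oft(config, ctx, outdir, rng_seeds):
    block = config.get("oft") or {}
    recordings = dict(ctx.get("recordings", {}))
    for group, path in (block.get("recordings") or {}).items():
        recordings[group] = io.read_recording_csv(_resolve(config, path))
    if not recordings:
        raise ConfigurationError("oft stage has no recordings: run simulate or configure paths")
    results = {}
    curves = []
    for group, rec in sorted(recordings.items()):
        mcv_300 = block.get("mcv_300")
        if mcv_300 is None and group in ctx.get("cells", {}):
            mcv_300 = float(ctx["cells"][group].v300.mean())
        res = oft.analyze_recording(rec, mcv_300=mcv_300)
        results[group] = {
            "h50_mosmol": res.h50,
            "h10_mosmol": res.h10,
            "h90_mosmol": res.h90,
            "w_mosmol": res.w,
            "asphericity_index_pct": res.asphericity_index,
        }
        curve = res.hemolysis_curve.assign(group=group)
        if res.mcv_osm_curve is not None:
            curve = curve.merge(res.mcv_osm_curve, on="osmolality_mosmol", how="left")
        curves.append(curve)
    pd.concat(curves).to_csv(outdir / "oft_curves.csv", index=False)
    io.write_results_json(results, outdir / "oft_results.json")
    return results


def _stage_micro(config, ctx, outdir, rng_seeds):
    block = config.get("micro") or {}
    datasets = dict(ctx.get("velocity_datasets", {}))
    for group, paths in (block.get("velocities") or {}).items():
        paths = paths if isinstance(paths, list) else [paths]
        datasets[group] = [
            io.read_velocity_dataset(_resolve(config, p), experiment_id=f"{group}/{i}")
            for i, p in enumerate(paths)
        ]
    if not datasets:
        raise ConfigurationError("micro stage has no velocity data: run simulate or configure paths")
    cutoff = float(block.get("cutoff_slow", micro.DEFAULT_CUTOFF_SLOW))
    bin_width = float(block.get("bin_width", 0.025))
    results = {}
    pdfs = []
    for group, dss in sorted(datasets.items()):
        res = micro.analyze_velocity_datasets(dss, cutoff_slow=cutoff, bin_width=bin_width)
        results[group] = {
            "slow_fraction_pct": res.slow_fraction_pct,
            "cutoff_slow_au": res.cutoff_slow,
            "occlusion_rate_pct": res.occlusion_rate_pct,
            "occlusion_se_pct": res.occlusion_se_pct,
            "n_experiments": len(dss),
        }
        pdfs.append(res.pdf.assign(group=group))
    pd.concat(pdfs).to_csv(outdir / "velocity_pdfs.csv", index=False)
    io.write_results_json(results, outdir / "micro_results.json")
    return results


def _stage_spectro(config, ctx, outdir, rng_seeds):
    block = config.get("spectro") or {}
    pairs = dict(ctx.get("spectra", {}))
    if "supernatant" in block and "lysate" in block:
        pairs["configured"] = (
            io.read_spectrum_csv(
                _resolve(config, block["supernatant"]),
                dilution_factor=float(block.get("dilution_supernatant", 20.0)),
            ),
            io.read_spectrum_csv(
                _resolve(config, block["lysate"]),
                dilution_factor=float(block.get("dilution_lysate", 200.0)),
                role="whole_lysate",
            ),
        )
    if not pairs:
        raise ConfigurationError("spectro stage has no spectra: run simulate or configure paths")
    results = {}
    for group, (sup, lys) in sorted(pairs.items()):
        species = hb_species_fractions(lys)
        results[group] = {
            "free_hb_pct": free_hb_percent(sup, lys),
            "species_fractions": species.fractions,
            "unmixing_residual": species.residual,
        }
    io.write_results_json(results, outdir / "spectro_results.json")
    return results


def _stage_hemocyto(config, ctx, outdir, rng_seeds):
    block = config.get("hemocyto") or {}
    results = {}
    cells = ctx.get("cells", {})
    if isinstance(block.get("volumes"), str):
        vols = pd.read_csv(_resolve(config, block["volumes"]))
        col = "v300_fl" if "v300_fl" in vols.columns else vols.columns[0]
        results["configured"] = {"hematology": vars(hemocyto.hematology_summary(vols[col]))}
    events = ctx.get("events", {})
    control_events = events.get("Control", (None, None))[0]
    for group in sorted(set(cells) | set(events)):
        entry = results.setdefault(group, {})
        if group in cells:
            entry["hematology"] = vars(hemocyto.hematology_summary(cells[group].v300))
        if group in events:
            stained, unstained = events[group]
            entry["positive_fraction_pct"] = hemocyto.positive_fraction(stained, unstained)
            if control_events is not None:
                entry["mfi_pct_of_control"] = hemocyto.mfi_percent(
                    stained, control_events, unstained
                )
    if not results:
        raise ConfigurationError("hemocyto stage has no inputs: run simulate or configure paths")
    io.write_results_json(results, outdir / "hemocyto_results.json")
    return results


def _stage_compare(config, ctx, outdir, rng_seeds):
    block = config.get("compare") or {}
    if "data" not in block:
        raise ConfigurationError("compare stage needs a 'data' CSV with columns group,value")
    table = pd.read_csv(_resolve(config, block["data"]))
    data = {g: grp["value"].to_numpy(float) for g, grp in table.groupby("group", sort=True)}
    comparison = stats.compare_groups(data, control=block.get("control"))
    io.write_results_json(comparison.to_dict(), outdir / "compare_results.json")
    return comparison.to_dict()


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "oft": _stage_oft,
    "micro": _stage_micro,
    "spectro": _stage_spectro,
    "hemocyto": _stage_hemocyto,
    "compare": _stage_compare,
}


def _write_plots(ctx, outdir):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "recordings" in ctx:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for group, rec in sorted(ctx["recordings"].items()):
            curve = oft.lysed_fraction_curve(rec)
            ax.plot(curve["osmolality_mosmol"], curve["lysed_pct"], marker="o", label=group)
        ax.invert_xaxis()
        ax.set_xlabel("osmolality (mOsmol)")
        ax.set_ylabel("lysed cells (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "hemolysis_curves.png", dpi=120)
        plt.close(fig)
    if "velocity_datasets" in ctx:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for group, dss in sorted(ctx["velocity_datasets"].items()):
            pdf = micro.velocity_pdf(dss)
            ax.plot(pdf["bin_center"], pdf["density_mean"], label=group)
        ax.axvline(micro.DEFAULT_CUTOFF_SLOW, color="r", ls="--", lw=1)
        ax.set_xlabel("normalized velocity (a.u.)")
        ax.set_ylabel("probability density")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "velocity_pdfs.png", dpi=120)
        plt.close(fig)


def run_pipeline(config, outdir=None) -> dict:
    """Execute the configured stages in order; returns per-stage results.

    ``config`` is a dict or a path to a YAML file.  The output directory is
    taken from the config (``outdir``, default ``results``) unless overridden.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stages = _validate(config)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir) if outdir is not None else _resolve(config, config.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)

    groups = (config.get("simulate") or {}).get("groups", ["Control", "TAX"])
    ss = np.random.SeedSequence(seed)
    keys = [f"simulate/{g}" for g in groups]
    rng_seeds = {
        k: int(s.generate_state(1)[0] & 0x7FFFFFFF) for k, s in zip(keys, ss.spawn(len(keys)))
    }

    logfile = outdir / "pipeline.log"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("erythrokit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("erythrokit %s; seed=%d; stages=%s", __version__, seed, stages)
        log.info("stage seeds: %s", rng_seeds)
        ctx: dict = {}
        results = {}
        for stage in stages:
            log.info("running stage %s", stage)
            results[stage] = _STAGE_FUNCS[stage](config, ctx, outdir, rng_seeds)
        if config.get("plots", False):
            _write_plots(ctx, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return results
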