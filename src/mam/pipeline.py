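"""Pipeline orchestration: build -> simulate -> analyze with manifests.

A run directory is driven by a single configuration mapping with per-stage
sections.  Each stage writes its outputs plus a manifest entry containing a
hash of the stage parameters (and of its upstream stage); re-running with an
unchanged configuration skips completed stages.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fc_bold, hierarchy, interaction_paths, meanfield, spike_stats
from .fixtures import make_small_multiarea, make_toy_bistable
from .model_spec import NetworkSpec, SynthParams, synth_connectome
from .simulator import simulate
from .spikeio import config_hash, read_spikes, write_spikes

log = logging.getLogger("mam.pipeline")

RUN_MANIFEST = "pipeline-manifest.json"


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


def _load_manifest(out_dir: Path) -> dict:
    path = out_dir / RUN_MANIFEST
    if path.exists():
        with open(path) as fh:
            return json.load(fh)
    return {}


def _save_manifest(out_dir: Path, manifest: dict) -> None:
    with open(out_dir / RUN_MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=1)


def build_network(cfg: dict) -> NetworkSpec:
    """Construct a network spec from a config section."""
    kind = cfg.get("kind", "synth")
    seed = int(cfg.get("seed", 0))
    params = dict(cfg.get("params", {}))
    if kind == "synth":
        n_areas = int(params.pop("n_areas", 4))
        return synth_connectome(n_areas, SynthParams(**params), seed=seed)
    if kind == "small_multiarea":
        return make_small_multiarea(seed=seed, **params)
    if kind == "toy_bistable":
        return make_toy_bistable(seed=seed, **params)
    if kind == "file":
        return NetworkSpec.from_json(params["path"])
    raise ValueError(f"unknown network kind {kind!r}")


def _stage_done(manifest: dict, stage: str, h: str, outputs: list[Path]) -> bool:
    return manifest.get(stage, {}).get("hash") == h and all(p.exists() for p in outputs)


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the requested stages; skip stages whose manifest hash matches.

    Stages: ``network`` (spec.json), ``simulate`` (spike files), ``analyze``
    with sub-sections stats, hierarchy, fc, granger, paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(out_dir)

    # ---- network -------------------------------------------------------
    net_cfg = config.get("network", {"kind": "small_multiarea"})
    net_hash = config_hash(net_cfg)
    spec_path = out_dir / "spec.json"
    if not _stage_done(manifest, "network", net_hash, [spec_path]):
        log.info("building network (%s)", net_cfg.get("kind", "synth"))
        spec = build_network(net_cfg)
        spec.to_json(spec_path)
        manifest["network"] = {"hash": net_hash, "params": net_cfg}
        _save_manifest(out_dir, manifest)
    spec = NetworkSpec.from_json(spec_path)

    # ---- simulate ------------------------------------------------------
    sim_cfg = config.get("simulate", {})
    sim_hash = config_hash([net_hash, sim_cfg])
    run_dir = out_dir / "run"
    if not _stage_done(manifest, "simulate", sim_hash, [run_dir / "manifest.json"]):
        duration = float(sim_cfg.get("duration_ms", 2000.0))
        seed = int(sim_cfg.get("seed", 0))
        log.info("simulating %.0f ms (seed %d)", duration, seed)
        spikes = simulate(
            spec,
            duration=duration,
            seed=seed,
            record_fraction=float(sim_cfg.get("record_fraction", 1.0)),
        )
        write_spikes(run_dir, spikes)
        manifest["simulate"] = {"hash": sim_hash, "params": sim_cfg}
        _save_manifest(out_dir, manifest)
    if not (run_dir / "manifest.json").exists():
        raise DependencyError("simulate stage output missing")
    spikes = read_spikes(run_dir)

    ana_cfg = config.get("analyze", {})
    discard = float(ana_cfg.get("discard_ms", 500.0))
    seed = int(ana_cfg.get("seed", 0))

    # ---- stats ---------------------------------------------------------
    stats_hash = config_hash([sim_hash, ana_cfg, "stats"])
    stats_path = out_dir / "stats.json"
    if not _stage_done(manifest, "stats", stats_hash, [stats_path]):
        log.info("computing spiking statistics")
        out = {}
        for label in spikes.populations:
            idx, t = spikes.trains[label]
            lvrs = [
                spike_stats.lvr(t[idx == i])
                for i in sorted(set(idx.tolist()))[:200]
            ]
            lvrs = [v for v in lvrs if np.isfinite(v)]
            out[label] = {
                "rate": spikes.mean_rate(label),
                "lvr": float(np.mean(lvrs)) if lvrs else None,
                "correlation": spike_stats.pairwise_correlation(
                    spikes, label, n_sample=200, seed=seed
                ),
            }
        with open(stats_path, "w") as fh:
            json.dump(out, fh, indent=1)
        manifest["stats"] = {"hash": stats_hash}
        _save_manifest(out_dir, manifest)

    # ---- area rate series (shared) --------------------------------------
    area_rates = {
        a: spike_stats.rate_histogram(spikes, a) for a in spec.grid.areas
    }

    # ---- hierarchy -----------------------------------------------------
    hier_hash = config_hash([sim_hash, ana_cfg, "hierarchy"])
    hier_path = out_dir / "hierarchy.json"
    if not _stage_done(manifest, "hierarchy", hier_hash, [hier_path]):
        log.info("fitting temporal hierarchy")
        start = int(discard)
        trimmed = {
            a: r.values[start:] for a, r in area_rates.items()
        }
        lags = hierarchy.lag_matrix(trimmed)
        hier = hierarchy.fit_hierarchy(lags, seed=seed)
        hier.violations = hierarchy.count_violations(hier, lags)
        smean, ssd, _ = hierarchy.surrogate_violations(
            lags, n_surrogates=int(ana_cfg.get("n_surrogates", 100)), seed=seed
        )
        pd.DataFrame(lags.tau, index=lags.areas, columns=lags.areas).to_csv(
            out_dir / "lags.csv"
        )
        with open(hier_path, "w") as fh:
            json.dump(
                {
                    "areas": hier.areas,
                    "levels": hier.levels.tolist(),
                    "objective": hier.objective,
                    "violations": hier.violations,
                    "surrogate_mean": smean,
                    "surrogate_sd": ssd,
                },
                fh,
                indent=1,
            )
        manifest["hierarchy"] = {"hash": hier_hash}
        _save_manifest(out_dir, manifest)

    # ---- fc (+ optional BOLD) -------------------------------------------
    fc_hash = config_hash([sim_hash, ana_cfg, "fc"])
    fc_path = out_dir / "fc.csv"
    if not _stage_done(manifest, "fc", fc_hash, [fc_path]):
        log.info("computing functional connectivity")
        pop_rates = {
            l: spike_stats.rate_histogram(spikes, l) for l in spec.grid.labels
        }
        inputs = fc_bold.synaptic_input_series(pop_rates, spec)
        fc = fc_bold.fc_matrix(inputs, discard_ms=discard)
        pd.DataFrame(fc.values, index=fc.areas, columns=fc.areas).to_csv(fc_path)
        if ana_cfg.get("bold", False):
            scale = inputs.values.max()
            norm = fc_bold.InputSeries(
                inputs.areas, inputs.values / scale if scale > 0 else inputs.values
            )
            bres = fc_bold.balloon_bold(norm)
            bold_fc = np.corrcoef(bres.bold[:, int(discard / 10.0) :])
            pd.DataFrame(bold_fc, index=fc.areas, columns=fc.areas).to_csv(
                out_dir / "fc_bold.csv"
            )
        labels = fc_bold.cluster_fc(fc, seed=seed)
        with open(out_dir / "fc_clusters.json", "w") as fh:
            json.dump(dict(zip(fc.areas, labels.tolist())), fh, indent=1)
        manifest["fc"] = {"hash": fc_hash}
        _save_manifest(out_dir, manifest)

    # ---- granger -------------------------------------------------------
    gr_hash = config_hash([sim_hash, ana_cfg, "granger"])
    gr_path = out_dir / "granger.csv"
    if not _stage_done(manifest, "granger", gr_hash, [gr_path]):
        log.info("computing conditional Granger causality")
        start = int(discard)
        rates = np.vstack(
            [spike_stats.rate_histogram(spikes, l).values[start:] for l in spec.grid.labels]
        )
        res = interaction_paths.granger_significance(
            rates, spec, alpha=float(ana_cfg.get("alpha", 0.05))
        )
        df = pd.DataFrame(res.pvalues, index=res.populations, columns=res.populations)
        df.to_csv(gr_path)
        manifest["granger"] = {"hash": gr_hash}
        _save_manifest(out_dir, manifest)

    # ---- paths ---------------------------------------------------------
    pa_hash = config_hash([sim_hash, ana_cfg, "paths"])
    pa_path = out_dir / "paths.json"
    if not _stage_done(manifest, "paths", pa_hash, [pa_path]):
        log.info("computing gain-matrix shortest paths")
        rates = np.array([spikes.mean_rate(l) for l in spec.grid.labels])
        G = interaction_paths.gain_matrix(spec, rates)
        Gp = interaction_paths.normalize_gain(G)
        report = interaction_paths.shortest_paths(Gp, spec.grid.labels)
        payload = {
            f"{report.labels[s]}->{report.labels[t]}": {
                "distance": d,
                "path": [report.labels[k] for k in report.path[(s, t)]],
            }
            for (s, t), d in report.distance.items()
        }
        with open(pa_path, "w") as fh:
            json.dump(payload, fh, indent=1)
        manifest["paths"] = {"hash": pa_hash}
        _save_manifest(out_dir, manifest)

    return out_dir
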