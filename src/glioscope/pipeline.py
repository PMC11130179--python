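"""End-to-end pipeline on a synthetic cohort.

``run_pipeline`` simulates a cohort (two tumor genotypes, several animals,
serial sessions), then runs every analysis stage — tumor dynamics, quiet-
wakefulness gating and widefield metrics, tumor-distance ratios, cellular
ensemble metrics — and the group-comparison layer, writing tidy CSV/JSON
outputs plus a run log with every parameter and derived seed.  A single
global seed determines all module seeds, so two runs with the same config
produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults, ensembles, gstats, io, spatial, synth, tumor, widefield
from .core import NeuronTraceSet

__all__ = ["default_config", "run_pipeline", "interaction_summary"]


def default_config() -> dict:
    """Demo cohort configuration: all analysis defaults, desk-scale sizes.

    The planted near/far amplitude gradients differ by genotype and
    concurrent expansion phase (strong distance dependence for 3xCR tumors
    during fast expansion, weak for GPC6), so the pipeline's comparison
    tables should recover a genotype-by-expansion interaction.
    """
    return {
        "seed": 1,
        "cohort": {
            "genotypes": ["3xCR", "GPC6"],
            "n_animals_per_genotype": 3,
            "session_days": [50, 54, 58, 62, 66, 70],
            "fast_onset_day": 58,
            "slow_slope_um2_per_day": 3.0e4,
            "fast_slope_um2_per_day": 2.0e5,
            "initial_radius_um": 500.0,
            "margin_jitter_sd_um": 20.0,
            "snapshot_pixel_um": 30.0,
            "snapshot_fov_px": 240,
            "movie_downsample_factor": 8,
            # near/far amplitude gradient factor per (genotype, class)
            "gradient_factors": {
                "3xCR": {"slow": 1.5, "fast": 2.8},
                "GPC6": {"slow": 1.3, "fast": 1.3},
            },
        },
        "widefield": {
            "frame_rate_hz": 5.0,
            "movie_duration_s": 340.0,
            "event_rate_hz": 0.1,
            "amplitude_dff": 5.0,
            "noise_sd_dff": 1.0,
            "event_duration_s": 1.0,
            "quiet_required_s": defaults.QUIET_REQUIRED_S,
            "run_threshold_m_s": defaults.RUN_SPEED_THRESHOLD_M_S,
            "k_sd": defaults.EVENT_K_SD,
        },
        "spatial": {
            "band_width_um": defaults.BAND_WIDTH_UM,
            "far_min_um": defaults.FAR_MIN_UM,
            "n_shuffles": 999,       # desk-scale; the full analysis uses 500000
        },
        "cellular": {
            "frame_rate_hz": 10.0,
            "duration_s": 240.0,
            "n_neurons": 60,
            "n_recordings_per_group": 2,
            "time_bins": ["early", "mid", "late"],
            "n_per_group": 100,
            # planted ensemble strength per genotype and bin (coactivation prob)
            "coactivation": {
                "3xCR": {"early": 0.9, "mid": 0.4, "late": 0.4},
                "GPC6": {"early": 0.4, "mid": 0.8, "late": 0.4},
            },
        },
        "stats": {"alpha": defaults.ALPHA},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def load_config(path_or_dict) -> dict:
    """Merge a user config (YAML path or dict) over the defaults."""
    if path_or_dict is None:
        return default_config()
    if isinstance(path_or_dict, (str, Path)):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict)
    return _merge(default_config(), user)


def _tumor_stage(cfg, rng_seeds, out_dir):
    """Simulate serial tumor snapshots per animal and analyze every interval."""
    c = cfg["cohort"]
    days = list(c["session_days"])
    fov = int(c["snapshot_fov_px"])
    px = float(c["snapshot_pixel_um"])
    center = (fov * px / 2, fov * px / 2)
    records, per_animal = [], {}
    for genotype in c["genotypes"]:
        for a in range(int(c["n_animals_per_genotype"])):
            animal = f"{genotype}-{a + 1}"
            phases = [((days[0], c["fast_onset_day"]), c["slow_slope_um2_per_day"]),
                      ((c["fast_onset_day"], days[-1] + 1),
                       c["fast_slope_um2_per_day"])]
            spec = synth.TumorGrowthSpec(
                center=center, initial_radius=c["initial_radius_um"],
                area_slope_per_phase=phases, session_days=days, pixel_size=px,
                fov_shape=(fov, fov), margin_jitter_sd=c["margin_jitter_sd_um"])
            images, truth = synth.generate_tumor_series(
                spec, seed=int(rng_seeds[animal]))
            for im in images:
                im.animal_id, im.genotype = animal, genotype
            recs = tumor.analyze_series(images)
            records.extend(recs)
            per_animal[animal] = {
                "genotype": genotype, "images": images, "truth": truth,
                "records": recs}
    table = pd.DataFrame([{
        "animal_id": r.animal_id, "genotype": r.genotype,
        "day_start": r.day_start, "day_end": r.day_end,
        "cv_per_day": r.cv_per_day, "expansion_rate_um2_per_day": r.expansion_rate,
        "expansion_class": r.expansion_class} for r in records])
    io.save_table(out_dir / "tumor_intervals.csv", table)
    pct = tumor.summarize_percentile_timecourse(records)
    io.save_table(out_dir / "cv_per_day_percentiles.csv", pct)
    return per_animal, table


def _pool_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    ny, nx = mask.shape[0] // factor, mask.shape[1] // factor
    trimmed = mask[: ny * factor, : nx * factor]
    return trimmed.reshape(ny, factor, nx, factor).mean(axis=(1, 3)) >= 0.5


def _widefield_stage(cfg, per_animal, rng, out_dir):
    """One widefield recording per interval: gate, detect, band-analyze."""
    c, wcfg, scfg = cfg["cohort"], cfg["widefield"], cfg["spatial"]
    factor = int(c["movie_downsample_factor"])
    movie_px = float(c["snapshot_pixel_um"]) * factor
    fs = float(wcfg["frame_rate_hz"])
    ratios, shuffle_rows = [], []
    for animal in sorted(per_animal):
        info = per_animal[animal]
        for rec in info["records"]:
            rec_seed = int(rng.integers(2 ** 31))
            rid = f"{animal}-d{rec.day_end}"
            # tumor geometry at the end of the interval, on the movie grid
            idx = [im.day for im in info["images"]].index(rec.day_end)
            mask = _pool_mask(info["truth"]["masks"][idx], factor)
            factor_nf = c["gradient_factors"][info["genotype"]][rec.expansion_class]
            mspec = synth.MovieSpec(
                duration_s=float(wcfg["movie_duration_s"]), frame_rate_hz=fs,
                fov_shape=mask.shape, pixel_size=movie_px,
                baseline_noise_sd=float(wcfg["noise_sd_dff"]),
                event_rate=float(wcfg["event_rate_hz"]),
                amplitude=float(wcfg["amplitude_dff"]),
                event_duration_s=float(wcfg["event_duration_s"]),
                distance_gradient=synth.DistanceGradient(
                    factor=factor_nf, near_um=float(scfg["band_width_um"]),
                    far_um=float(scfg["far_min_um"])),
                seed=rec_seed)
            movie, _, _ = synth.generate_movie(mspec, tumor_mask=mask)
            bspec = synth.BehaviorSpec(
                duration_s=float(wcfg["movie_duration_s"]), sample_rate_hz=fs,
                run_bouts=[(20.0, 30.0, 0.05)], whisk_bouts=[(50.0, 60.0, 1.0)],
                seed=rec_seed + 1)
            quiet = widefield.detect_quiet_epochs(
                synth.generate_behavior(bspec),
                run_threshold=float(wcfg["run_threshold_m_s"]),
                required_s=float(wcfg["quiet_required_s"]))
            metrics = widefield.compute_pixel_metrics(movie, quiet,
                                                      k=float(wcfg["k_sd"]))
            dmap = spatial.distance_map(mask, movie_px,
                                        band_width=float(scfg["band_width_um"]))
            for name in widefield.METRIC_NAMES:
                ratios.append(spatial.near_far_ratio(
                    metrics.metric(name), dmap,
                    near_max=float(scfg["band_width_um"]),
                    far_min=float(scfg["far_min_um"]),
                    metric=name, recording_id=rid,
                    expansion_class=rec.expansion_class,
                    genotype=info["genotype"]))
            m, d = spatial.raster_vectors(metrics.mean_amplitude, dmap)
            res = spatial.shuffle_regression(
                m, d, n_shuffles=int(scfg["n_shuffles"]), seed=rec_seed + 2)
            shuffle_rows.append({"recording_id": rid, "metric": "mean_amplitude",
                                 "genotype": info["genotype"],
                                 "expansion_class": rec.expansion_class,
                                 **asdict(res)})
    ratio_table = spatial.group_ratios(ratios)
    io.save_table(out_dir / "near_far_ratios.csv", ratio_table)
    shuffle_table = pd.DataFrame(shuffle_rows)
    io.save_table(out_dir / "shuffle_regression.csv", shuffle_table)
    (out_dir / "shuffle_regression.json").write_text(
        json.dumps(shuffle_rows, indent=1, default=float))
    return ratio_table, shuffle_table


def _cellular_stage(cfg, rng, out_dir):
    """Planted ensembles per genotype and time bin; metrics + pooled groups."""
    ccfg = cfg["cellular"]
    fs = float(ccfg["frame_rate_hz"])
    tables: dict[str, list[pd.DataFrame]] = {}
    for genotype in cfg["cohort"]["genotypes"]:
        for tb in ccfg["time_bins"]:
            label = f"{genotype}|{tb}"
            tables[label] = []
            for r in range(int(ccfg["n_recordings_per_group"])):
                pspec = synth.PopulationSpec(
                    n_neurons=int(ccfg["n_neurons"]), n_clusters=2,
                    cluster_sizes=[10, 10],
                    within_cluster_coactivation_prob=float(
                        ccfg["coactivation"][genotype][tb]),
                    background_rate=0.1, ar_decay=0.9,
                    transient_amplitude=1.0, noise_sd=0.1,
                    frame_rate_hz=fs, duration_s=float(ccfg["duration_s"]),
                    seed=int(rng.integers(2 ** 31)))
                dff, _, _, positions = synth.generate_population(pspec)
                ddff = ensembles.deconvolve_matrix(dff, pspec.ar_decay,
                                                   noise_sd=pspec.noise_sd)
                graph = ensembles.correlation_graph(ddff)
                table = ensembles.neuron_metrics_table(ddff, fs, graph=graph)
                table["genotype"], table["time_bin"] = genotype, tb
                tables[label].append(table)
    pooled = ensembles.assemble_groups(tables, int(ccfg["n_per_group"]),
                                       seed=int(rng.integers(2 ** 31)))
    io.save_table(out_dir / "cellular_metrics.csv", pooled)
    return pooled


def _stats_stage(cfg, ratio_table, pooled, out_dir):
    alpha = float(cfg["stats"]["alpha"])
    rows = []
    for metric, sub in ratio_table[ratio_table["defined"]].groupby("metric"):
        groups = {f"{g}|{c}": s["ratio"].to_numpy()
                  for (g, c), s in sub.groupby(["genotype", "expansion_class"])
                  if len(s) >= 2}
        if len(groups) < 3:
            continue
        omni, results = gstats.kruskal_wallis_mc(groups, alpha=alpha)
        t = gstats.comparison_table(results)
        t.insert(0, "family", f"near_far_ratio:{metric}")
        t["omnibus_H"], t["omnibus_p"] = omni["H"], omni["p_value"]
        rows.append(t)
    if not pooled.empty:
        for metric in ("ddff_per_min", "events_per_sec", "mean_amplitude",
                       "clustering_coefficient"):
            groups = {g: s[metric].to_numpy()
                      for g, s in pooled.groupby("group") if len(s) >= 2}
            if len(groups) < 3:
                continue
            omni, results = gstats.kruskal_wallis_mc(groups, alpha=alpha)
            t = gstats.comparison_table(results)
            t.insert(0, "family", f"cellular:{metric}")
            t["omnibus_H"], t["omnibus_p"] = omni["H"], omni["p_value"]
            rows.append(t)
    table = (pd.concat(rows, ignore_index=True) if rows else pd.DataFrame())
    io.save_table(out_dir / "comparisons.csv", table)
    return table


def interaction_summary(ratio_table: pd.DataFrame,
                        metric: str = "mean_amplitude") -> pd.DataFrame:
    """Mean near/far ratio per (genotype, expansion class) for one metric."""
    sub = ratio_table[(ratio_table["metric"] == metric) & ratio_table["defined"]]
    return (sub.groupby(["genotype", "expansion_class"])["ratio"]
            .agg(["mean", "sem", "count"]).reset_index())


def run_pipeline(config=None, output_dir="pipeline_output") -> dict:
    """Run simulate -> tumor -> widefield -> spatial -> cellular -> stats.

    Returns a dict of result tables; all outputs are also written under
    ``output_dir`` together with ``run_log.json`` recording the full config
    and every derived seed.
    """
    cfg = load_config(config)
    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(int(cfg["seed"]))
    animal_seeds = {}
    c = cfg["cohort"]
    for genotype in c["genotypes"]:
        for a in range(int(c["n_animals_per_genotype"])):
            animal_seeds[f"{genotype}-{a + 1}"] = int(master.integers(2 ** 31))

    per_animal, interval_table = _tumor_stage(cfg, animal_seeds, out_dir)
    ratio_table, shuffle_table = _widefield_stage(cfg, per_animal, master, out_dir)
    pooled = _cellular_stage(cfg, master, out_dir)
    comparisons = _stats_stage(cfg, ratio_table, pooled, out_dir)
    summary = interaction_summary(ratio_table)
    io.save_table(out_dir / "interaction_summary.csv", summary)

    (out_dir / "run_log.json").write_text(json.dumps(
        {"config": cfg, "animal_seeds": animal_seeds}, indent=1, default=str))
    return {"intervals": interval_table, "ratios": ratio_table,
            "shuffle": shuffle_table, "cellular": pooled,
            "comparisons": comparisons, "interaction": summary,
            "output_dir": str(out_dir)}
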