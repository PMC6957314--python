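"""Pipeline orchestration: simulate -> detect -> cycles -> metrics ->
refractory -> stats, with serialized tables and figures.

Figures are derived strictly from the written tables so numerical results
never depend on plotting code.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import RecordingBundle, read_bundle
from .cycles import ibi_summary, segment_cycles
from .detect import BurstDetectParams, detect_population_bursts, population_burst_stats
from .metrics import (
    burst_spiking,
    classify_pre_i,
    onset_jitter,
    onset_times,
    ramp_fits,
    shape_profile,
)
from .refractory import (
    assemble_trials,
    evoked_probability,
    fit_sigmoid,
    refractory_period,
    spontaneous_cdf,
)
from .stats import anova_bonferroni, linear_regression, paired_t, welch_t
from .synth import generate_stim_experiment, preset, simulate_bundle

log = logging.getLogger(__name__)

_TESTS = {
    "paired_t": paired_t,
    "welch_t": welch_t,
    "anova_bonferroni": anova_bonferroni,
    "linear_regression": linear_regression,
}

DEFAULT_CONFIG = {
    "preset": "baseline",
    "n_cycles": 100,
    "neurons": {"exc_preI": 3, "exc_nonpreI": 3, "inhibitory": 2},
    "n_pulses": 60,
    "seed": 1,
    "detect": {},
    "refractory": {"bin_width": 0.5, "criterion": 0.9},
    "comparisons": [],
}


def validate_config(config: dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    for comp in cfg["comparisons"]:
        if comp.get("test") not in _TESTS:
            raise ValueError(f"comparison names unimplemented test: {comp.get('test')!r}")
    if "bundle" not in cfg and cfg.get("preset") not in ("baseline", "SP"):
        raise ValueError(f"unknown preset {cfg.get('preset')!r}")
    return cfg


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Deterministic given the config's seed.  Returns the report dict.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    if "bundle" in cfg:
        bundle = read_bundle(cfg["bundle"])
        condition = next(iter(bundle.condition_windows))
        synth_cfg = None
    else:
        synth_cfg = preset(cfg["preset"])
        condition = cfg["preset"]
        bundle, _ = simulate_bundle(synth_cfg, cfg["n_cycles"], cfg["neurons"], seed)

    # --- detect + cycles ---------------------------------------------------
    params = BurstDetectParams(**cfg.get("detect", {}))
    trace = next(t for t in bundle.traces.values() if t.role == "population_integrated")
    bursts = detect_population_bursts(trace, params)
    pd.DataFrame(
        {
            "onset_s": [b.onset for b in bursts],
            "offset_s": [b.offset for b in bursts],
            "peak_s": [b.peak_time for b in bursts],
            "peak_amp": [b.peak_amplitude for b in bursts],
            "duration_s": [b.duration for b in bursts],
            "halfwidth_s": [b.halfwidth for b in bursts],
        }
    ).to_csv(out / "bursts.csv", index=False, float_format="%.9g")
    cycleset = segment_cycles(bursts, condition=condition)
    cycleset.to_frame().to_csv(out / "cycles.csv", index=False, float_format="%.9g")
    summary = ibi_summary(cycleset)
    burst_stats = population_burst_stats(bursts)

    # --- per-neuron metrics -------------------------------------------------
    rows = []
    onset_rows = []
    for nid, rec in sorted(bundle.neurons.items()):
        spikes = rec.spikes.get(condition)
        if spikes is None or len(spikes) == 0:
            continue
        try:
            pre_i = classify_pre_i(spikes, cycleset)
        except ValueError:
            pre_i = False
        row = {"neuron_id": nid, "class": rec.cls, "condition": condition, "pre_i": pre_i}
        try:
            bs = burst_spiking(spikes, cycleset)
            row.update(
                burst_freq_hz=bs.mean_frequency,
                burst_dur_s=bs.mean_duration,
                burst_count=bs.mean_count,
            )
        except ValueError:
            log.info("neuron %s has no burst spiking; metrics skipped", nid)
            continue
        try:
            prof = shape_profile(spikes, cycleset)
            row["peak_position_pct"] = prof.peak_position
        except ValueError:
            row["peak_position_pct"] = np.nan
        fits = ramp_fits(spikes, cycleset)
        if fits:
            row["ibi_mean_rate_hz"] = float(np.mean([f.ibi_mean_rate for f in fits]))
            row["ramp_slope_hz_per_s"] = float(np.mean([f.slope for f in fits]))
        rule = "max_rate_change" if pre_i else "first_spike"
        series = onset_times(spikes, cycleset, rule)
        if len(series.latencies) >= 3:
            row["onset_jitter_ln_rmssd"] = onset_jitter(series)
            for k, lat in enumerate(series.latencies):
                onset_rows.append((nid, k, lat))
        rows.append(row)
    metrics_df = pd.DataFrame(rows)
    metrics_df.to_csv(out / "neuron_metrics.csv", index=False, float_format="%.9g")
    pd.DataFrame(onset_rows, columns=["neuron_id", "cycle", "latency_s"]).to_csv(
        out / "onset_latencies.csv", index=False, float_format="%.9g"
    )

    # --- refractory assay ----------------------------------------------------
    refr = None
    rcfg = cfg.get("refractory", {})
    if synth_cfg is not None or bundle.pulses:
        if bundle.pulses:
            pulses, stim_bursts = bundle.pulses, bursts
        else:
            pulses, stim_bursts, _ = generate_stim_experiment(
                synth_cfg, cfg.get("n_pulses", 60), seed + 1
            )
        trials = assemble_trials(pulses, stim_bursts)
        curve = evoked_probability(trials, bin_width=rcfg.get("bin_width", 0.5))
        spont = segment_cycles(
            [b for i, b in enumerate(stim_bursts)], condition=condition
        )
        cdf = spontaneous_cdf(spont, curve.bin_edges)
        fit = fit_sigmoid(curve)
        rp = refractory_period(fit, rcfg.get("criterion", 0.9))
        refr = {
            "n_trials": len(trials),
            "n_included": sum(not t.excluded for t in trials),
            "bin_edges_s": curve.bin_edges.tolist(),
            "evoked_probability": np.where(
                np.isnan(curve.probabilities), None, curve.probabilities
            ).tolist(),
            "trial_counts": curve.counts.tolist(),
            "spontaneous_cdf": cdf.probabilities.tolist(),
            "sigmoid_fit": {
                "t50_s": fit.t50,
                "steepness_s": fit.steepness,
                "plateau": fit.plateau,
                "rss": fit.rss,
            },
            "refractory_period_s": rp,
        }
        (out / "refractory.json").write_text(json.dumps(refr, indent=2) + "\n")

    # --- statistics ----------------------------------------------------------
    stat_entries = []
    for comp in cfg["comparisons"]:
        fn = _TESTS[comp["test"]]
        groups = [metrics_df.loc[metrics_df["class"] == g, comp["metric"]].dropna().to_numpy()
                  for g in comp["groups"]]
        res = fn(*groups) if comp["test"] != "anova_bonferroni" else fn(groups)
        stat_entries.append(
            {
                "metric": comp["metric"],
                "groups": comp["groups"],
                "method": res.method,
                "statistic": res.statistic,
                "p": res.p_two_sided,
                "tier": res.tier,
            }
        )
    (out / "stats_report.json").write_text(
        json.dumps({"comparisons": stat_entries}, indent=2) + "\n"
    )

    report = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "condition": condition,
        "n_bursts": len(bursts),
        "ibi_summary": {
            "mean_ibi_s": summary.mean_ibi,
            "sd_ibi_s": summary.sd_ibi,
            "frequency_hz": summary.frequency,
            "n_cycles": summary.n_cycles,
        },
        "burst_stats": {
            "mean_duration_s": burst_stats["mean_duration"],
            "mean_halfwidth_s": burst_stats["mean_halfwidth"],
        },
        "refractory": refr,
        "stats": stat_entries,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def make_figures(report_dir) -> list:
    """Render figures from the serialized report tables only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(report_dir)
    made = []

    cyc_path = out / "cycles.csv"
    if not cyc_path.exists():
        raise FileNotFoundError("missing table: cycles.csv")
    cycles = pd.read_csv(cyc_path)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(cycles["ibi_s"], bins=20, color="0.4")
    ax.set_xlabel("inter-burst interval (s)")
    ax.set_ylabel("cycles")
    fig.tight_layout()
    f = out / "fig_ibi_hist.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    made.append(f)

    refr_path = out / "refractory.json"
    if refr_path.exists():
        refr = json.loads(refr_path.read_text())
        edges = np.asarray(refr["bin_edges_s"])
        centers = (edges[:-1] + edges[1:]) / 2
        probs = [np.nan if p is None else p for p in refr["evoked_probability"]]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(centers, probs, "o-", label="evoked probability")
        ax.plot(edges[1:], refr["spontaneous_cdf"], "s--", label="spontaneous IBI CDF")
        ax.axvline(refr["refractory_period_s"], color="r", lw=1, label="refractory period")
        ax.set_xlabel("elapsed time since preceding burst onset (s)")
        ax.set_ylabel("probability")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        f = out / "fig_refractory.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        made.append(f)

    lat_path = out / "onset_latencies.csv"
    if lat_path.exists():
        lat = pd.read_csv(lat_path)
        fig, ax = plt.subplots(figsize=(4, 4))
        for nid, g in lat.groupby("neuron_id"):
            v = g.sort_values("cycle")["latency_s"].to_numpy() * 1000
            ax.plot(v[:-1], v[1:], ".", ms=3, alpha=0.6)
        ax.set_xlabel("onset latency i (ms)")
        ax.set_ylabel("onset latency i+1 (ms)")
        ax.set_title("Poincaré plot of burst-onset latencies", fontsize=9)
        fig.tight_layout()
        f = out / "fig_poincare.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        made.append(f)
    return made
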