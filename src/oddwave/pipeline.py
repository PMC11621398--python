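"""End-to-end orchestration: simulate → preprocess → ERP/ERSP/PSD → stats.

``run_pipeline`` produces one directory of tidy CSV/JSON tables per run —
component scores, band-max ERSP summaries, resting band powers, drinking
metrics, group ANOVAs and the marker-by-phenotype correlation matrix —
plus a QC log of rejection counts per stage. Deterministic given the config
seed; per-subject randomness is derived with ``np.random.SeedSequence``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import consumption, erp, io, presets, preprocessing, resting, stats, synthetic, timefreq
from .config import PipelineConfig

log = logging.getLogger("oddwave")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        return wrapper
    return deco


def _channel_names(n: int) -> tuple[str, ...]:
    if n == 9:
        return synthetic.CHANNEL_NAMES
    return tuple(f"ch{i + 1}" for i in range(n))


def simulate_subject(cfg: PipelineConfig, preset: str, subject_seed: int):
    """One animal's oddball recording, resting recording and ground truth."""
    rng = np.random.default_rng(subject_seed)
    schedule = synthetic.build_schedule(
        cfg.n_standards, cfg.n_deviants, cfg.n_blocks, cfg.isi_s,
        seed=int(rng.integers(2**31)), block_gap_s=cfg.block_gap_s,
    )
    truth = presets.subject_truth(
        presets.make_truth(
            preset, noise_sd_uv=cfg.noise_sd_uv,
            background_level_uv2_hz=cfg.background_level_uv2_hz,
            artifact_spec=synthetic.ArtifactSpec(count=cfg.artifact_count),
        ),
        rng,
    )
    names = _channel_names(cfg.n_channels)
    oddball = synthetic.simulate_oddball_recording(schedule, truth, channel_names=names)
    rest = synthetic.simulate_resting(truth, cfg.resting_duration_s, channel_names=names)
    return oddball, rest, truth


@_stage("preprocess")
def preprocess_recording(cfg: PipelineConfig, rec):
    spec = preprocessing.FilterSpec(cfg.filter_low_hz, cfg.filter_high_hz,
                                    cfg.filter_beta, cfg.filter_transition_hz)
    filtered = preprocessing.filter_recording(rec, spec)
    epochs = preprocessing.extract_epochs(filtered, window_s=cfg.epoch_window_s,
                                          baseline_window_s=cfg.baseline_window_s)
    return preprocessing.reject_artifacts(epochs, cfg.delta_uv, cfg.channel_drop_fraction)


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run every stage for every preset cohort; returns the result tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    subj_ss, drink_ss = root.spawn(2)
    subject_seeds = subj_ss.generate_state(len(cfg.presets) * cfg.n_subjects) % (2**31)

    erp_rows, ersp_rows, psd_rows, qc = [], [], [], {}
    spec = preprocessing.FilterSpec(cfg.filter_low_hz, cfg.filter_high_hz,
                                    cfg.filter_beta, cfg.filter_transition_hz)
    idx = 0
    for preset in cfg.presets:
        for s in range(cfg.n_subjects):
            subject = f"{preset}-{s + 1:02d}"
            oddball, rest, truth = _stage("simulate")(simulate_subject)(
                cfg, preset, int(subject_seeds[idx]))
            idx += 1
            epochs = preprocess_recording(cfg, oddball)
            qc[subject] = epochs.qc

            table = _stage("erp")(erp.component_table)(
                {subject: epochs}, {subject: preset})
            erp_rows.append(table)

            ch_idx = [oddball.channel_index(c) for c in cfg.ersp_channels]
            emap = _stage("ersp")(timefreq.compute_ersp)(
                epochs, synthetic.DEVIANT, cfg.ersp_window_samples,
                cfg.ersp_pad_ratio, cfg.ersp_n_times, channels=ch_idx,
                baseline_window_s=cfg.baseline_window_s if cfg.ersp_baseline else None,
            )
            bm = timefreq.band_max_table(emap)
            bm.insert(0, "subject", subject)
            bm.insert(1, "group", preset)
            ersp_rows.append(bm)

            rest_f = preprocessing.filter_recording(rest, spec)
            psd = _stage("psd")(resting.welch_psd)(
                rest_f, segment_s=cfg.psd_segment_s, overlap=cfg.psd_overlap,
                delta_uv=cfg.delta_uv)
            bp = resting.band_power_table(psd, mode=cfg.band_aggregation)
            bp.insert(0, "subject", subject)
            bp.insert(1, "group", preset)
            psd_rows.append(bp)
            log.info("finished subject %s", subject)

    erp_table = pd.concat(erp_rows, ignore_index=True)
    ersp_table = pd.concat(ersp_rows, ignore_index=True)
    psd_table = pd.concat(psd_rows, ignore_index=True)

    # group statistics: between-subjects ANOVA (treatment x channel) per marker
    anova_rows = []
    if len(cfg.presets) >= 2:
        for comp in ("P1N1", "N1P2", "P2N2", "N2P3"):
            sub = erp_table[erp_table["component"] == comp]
            if sub["group"].nunique() < 2:
                continue
            res = _stage("stats")(stats.between_anova)(
                sub.rename(columns={"amplitude_uv": "value"}), "value",
                ("group", "channel"))
            res.insert(0, "marker", comp)
            anova_rows.append(res)
    anova_table = (pd.concat(anova_rows, ignore_index=True)
                   if anova_rows else pd.DataFrame())
    if not anova_table.empty:
        treat = anova_table[anova_table["Source"] == "group"].copy()
        treat["p_adj"] = stats.sidak_adjust(treat["p"].to_numpy())
        anova_table = anova_table.merge(
            treat[["marker", "Source", "p_adj"]], on=["marker", "Source"], how="left")

    # drinking phenotypes + correlations for the dependent cohort
    corr_table = pd.DataFrame()
    metrics_table = pd.DataFrame()
    if "dependent" in cfg.presets:
        profile = _stage("consumption")(synthetic.simulate_drinking)(
            n_rats=cfg.n_subjects, bl_means=cfg.drinking_bl_means,
            ade_increments=cfg.drinking_ade_increments,
            noise_sd=cfg.drinking_noise_sd, between_sd=cfg.drinking_between_sd,
            seed=int(drink_ss.generate_state(1)[0] % (2**31)),
        )
        metrics_table = consumption.compute_metrics(profile)
        dep = erp_table[(erp_table["group"] == "dependent")
                        & erp_table["component"].isin(["P1N1", "N1P2", "P2N2"])]
        markers = (
            stats.average_channels(dep, "amplitude_uv", by=("component",))
            .pivot(index="subject", columns="component", values="amplitude_uv")
        )
        markers.index = [f"rat{i + 1:02d}" for i in range(len(markers))]
        drink = metrics_table[metrics_table["solution"] == "total"].pivot(
            index="animal", columns="metric", values="value")
        corr_table = _stage("stats")(stats.correlation_matrix)(
            markers, drink, adjust=cfg.sidak_scope)

    tables = {
        "erp_components": erp_table, "ersp_band_max": ersp_table,
        "resting_band_power": psd_table, "anova": anova_table,
        "drinking_metrics": metrics_table, "correlations": corr_table,
    }
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)
    (out / "qc.json").write_text(json.dumps(qc, indent=1))
    cfg.to_yaml(out / "config.yaml")
    return tables
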