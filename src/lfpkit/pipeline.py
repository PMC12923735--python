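"""Full-pipeline orchestration from a single config with a
machine-readable run report.

All randomness flows from one master seed; each stage derives a child
seed as ``SeedSequence([master_seed, crc32(stage_name)])`` so every
stage is independently reproducible.  Regenerating with the same config
and seed yields an identical report (timestamps excluded from the
comparison by construction: the report carries none).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict
from typing import Any

import numpy as np

from . import __version__
from .events import (detect_epileptiform, detect_fast_ripples,
                     detect_ripples, exclude_overlapping, summarize_events)
from .pac import (default_comodulogram_grids, comodulogram, pac)
from .photometry import auc, event_aligned, isosbestic_check
from .signal import (BAND_PRESETS, BandDef, ContinuousSignal,
                     ValidationError)
from .spectral import band_powers, psd_per_segment
from .spikes import (build_units, classify_units, detect_spikes,
                     flag_cross_channel_artifacts, qc_unit,
                     waveform_features)
from .synth import (EventSpec, LfpSpec, PhotoSpec, SpikeClassSpec,
                    SpikePopSpec, TransientSpec, gen_lfp, gen_photometry,
                    gen_spikes)

_KNOWN_KEYS = {
    "lfp", "spikes", "photometry", "bands", "pac", "events",
    "spike_detection", "segment_s", "comodulogram", "label"
}


def child_seed(master_seed: int, stage: str) -> int:
    """Documented seed-derivation rule: stage name -> child seed."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def validate_config(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")


def _bands_from_config(config: dict) -> list[BandDef]:
    names = config.get("bands",
                       ["theta", "low_gamma", "high_gamma", "ripple"])
    out = []
    for nm in names:
        if isinstance(nm, str):
            if nm not in BAND_PRESETS:
                raise ValidationError(f"unknown band preset {nm!r}")
            out.append(BAND_PRESETS[nm])
        else:
            out.append(BandDef(**nm))
    return out


def run_pipeline(config: dict, seed: int) -> dict:
    """Execute simulate -> spectral -> pac -> events -> spikes ->
    photometry and collect a report.

    The config is validated before any computation; a stage failure
    aborts with the completed stages recorded in the raised error's
    report attribute.
    """
    validate_config(config)
    report: dict[str, Any] = {
        "tool_version": __version__,
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "warnings": [],
        "stages_completed": [],
    }
    bands = _bands_from_config(config)
    segment_s = float(config.get("segment_s", 300.0))

    # --- simulate / load LFP -------------------------------------------
    lfp_cfg = dict(config.get("lfp", {}))
    events_cfg = lfp_cfg.pop("events", [])
    spec = LfpSpec(**lfp_cfg,
                   events=[EventSpec(**e) for e in events_cfg])
    sig, truth = gen_lfp(spec, child_seed(seed, "lfp"))
    report["stages_completed"].append("simulate_lfp")

    # --- spectral -------------------------------------------------------
    psd_res = psd_per_segment(sig, segment_s)
    bp = band_powers(psd_res, bands)
    report["band_power"] = {k: [float(x) for x in v] for k, v in bp.items()}
    report["stages_completed"].append("spectral")

    # --- pac ------------------------------------------------------------
    pac_cfg = config.get("pac", {})
    low = BandDef("pac_low", *pac_cfg.get("low", (4.0, 12.0)))
    high = BandDef("pac_high", *pac_cfg.get("high", (30.0, 80.0)))
    channel = pac_cfg.get("channel", 0)
    pr = pac(sig, low, high, channel)
    report["pac"] = {"MIn": pr.MIn, "MIn_normalized": pr.MIn_normalized,
                     "n": pr.n,
                     "low": [low.f_lo, low.f_hi],
                     "high": [high.f_lo, high.f_hi]}
    if config.get("comodulogram", False):
        lo_grid, hi_grid = default_comodulogram_grids()
        como = comodulogram(sig, lo_grid, hi_grid, channel)
        report["comodulogram"] = como.tolist()
    report["stages_completed"].append("pac")

    # --- events ---------------------------------------------------------
    ev_cfg = config.get("events", {})
    epi = detect_epileptiform(
        sig,
        sd_mult=ev_cfg.get("sd_mult", 4.0),
        min_channels_contig=ev_cfg.get("min_channels_contig", 5),
        max_duration_s=ev_cfg.get("max_duration_s", 4.0),
        hf_cut_hz=ev_cfg.get("hf_cut_hz", 100.0),
    )
    ripples = detect_ripples(sig, channel=ev_cfg.get("channel", 0))
    ripples = exclude_overlapping(ripples, epi)
    report["epileptiform"] = _summary_dict(
        summarize_events(epi, sig.duration_s, segment_s))
    report["ripples"] = _summary_dict(
        summarize_events(ripples, sig.duration_s, segment_s))
    if sig.fs > 2 * 500.0:  # fast-ripple band needs headroom above 500 Hz
        fr = exclude_overlapping(
            detect_fast_ripples(sig, channel=ev_cfg.get("channel", 0)), epi)
        report["fast_ripples"] = _summary_dict(
            summarize_events(fr, sig.duration_s, segment_s))
    report["stages_completed"].append("events")

    # --- spikes ---------------------------------------------------------
    if "spikes" in config:
        sp_cfg = dict(config["spikes"])
        classes = sp_cfg.pop("classes", None)
        spk_spec = SpikePopSpec(**sp_cfg) if classes is None else \
            SpikePopSpec(**sp_cfg,
                         classes=[SpikeClassSpec(**c) for c in classes])
        spike_sig, spike_truth = gen_spikes(spk_spec,
                                            child_seed(seed, "spikes"))
        det_cfg = config.get("spike_detection", {})
        cands = detect_spikes(spike_sig,
                              sd_mult=det_cfg.get("sd_mult", 3.0))
        cands = flag_cross_channel_artifacts(
            cands,
            coincidence_window_ms=det_cfg.get("coincidence_window_ms", 0.5),
            min_channels=det_cfg.get("min_channels", 6))
        units = build_units(cands, spike_sig.fs, spike_sig.duration_s)
        for u in units:
            qc_unit(u)
            waveform_features(u)
        units = classify_units(units, seed=child_seed(seed, "classify"))
        report["units"] = [{
            "unit_id": u.unit_id,
            "n_spikes": u.n_spikes,
            "firing_rate_hz": u.firing_rate_hz,
            "label": u.label,
            "included": u.qc.get("included", False),
            "features": {k: float(v) for k, v in u.features.items()},
        } for u in units]
        report["stages_completed"].append("spikes")

    # --- photometry -----------------------------------------------------
    if "photometry" in config:
        ph_cfg = dict(config["photometry"])
        transients = [TransientSpec(**tr)
                      for tr in ph_cfg.pop("transients", [])]
        ph_spec = PhotoSpec(**ph_cfg, transients=transients)
        rec, _ = gen_photometry(ph_spec, child_seed(seed, "photometry"))
        if rec.event_tags:
            tr470 = event_aligned(rec, "470")
            per_event, mean_auc = auc(tr470)
            iso = isosbestic_check(rec)
            report["photometry"] = {
                "n_events": tr470.matrix.shape[0],
                "auc_per_event": [float(v) for v in per_event],
                "mean_auc": mean_auc,
                "mean_peak_dff": float(tr470.mean.max()),
                "isosbestic_mean_correlation": iso["mean_correlation"],
            }
        report["stages_completed"].append("photometry")

    return report


def _summary_dict(s) -> dict:
    return {
        "n_events": s.n_events,
        "event_rate_per_min": s.event_rate_per_min,
        "mean_intra_freq_hz": s.mean_intra_freq_hz,
        "mean_peak_amplitude": s.mean_peak_amplitude,
        "mean_duration_s": s.mean_duration_s,
        "per_segment_counts": s.per_segment_counts,
        "per_segment_rates_per_min": s.per_segment_rates_per_min,
    }


# ---------------------------------------------------------------------------
# demo configs and condition comparison
# ---------------------------------------------------------------------------

def demo_config(condition: str = "WT") -> dict:
    """Two demonstration parameterisations.

    ``WT`` — intact theta-gamma coupling, no pathological events;
    ``KI`` — weakened coupling plus injected epileptiform discharges and
    fast ripples, emulating the late-stage disease phenotype.
    """
    base = {
        "label": condition,
        "lfp": {
            "fs": 2000.0, "duration_s": 60.0, "n_channels": 8,
            "theta_hz": 6.0, "gamma_hz": 40.0,
            "theta_amp": 1.0, "gamma_amp": 0.4, "noise_sd": 0.5,
        },
        "bands": ["theta", "low_gamma", "high_gamma", "ripple"],
        "pac": {"low": (4.0, 12.0), "high": (30.0, 80.0), "channel": 0},
        "segment_s": 300.0,
    }
    if condition == "WT":
        base["lfp"]["coupling_depth"] = 0.8
        base["lfp"]["events"] = []
    elif condition == "KI":
        base["lfp"]["coupling_depth"] = 0.2
        base["lfp"]["events"] = [
            {"kind": "epileptiform", "t_on": 12.0, "duration_s": 1.5,
             "carrier_hz": 150.0, "amplitude": 6.0,
             "channels": [0, 1, 2, 3, 4, 5]},
            {"kind": "epileptiform", "t_on": 33.0, "duration_s": 2.0,
             "carrier_hz": 180.0, "amplitude": 6.0,
             "channels": [1, 2, 3, 4, 5, 6]},
            {"kind": "fast_ripple", "t_on": 48.0, "duration_s": 0.08,
             "carrier_hz": 300.0, "amplitude": 5.0, "channels": [2]},
        ]
    else:
        raise ValidationError(f"unknown demo condition {condition!r}")
    return base


def compare_conditions(report_a: dict, report_b: dict) -> dict:
    """Descriptive differences between two run reports (no statistics).

    Ratios are reported as ``None`` (absent) when the denominator is 0,
    never as infinity.
    """
    if set(report_a.get("band_power", {})) != set(report_b.get(
            "band_power", {})):
        raise ValidationError("reports use different band presets")

    def _ratio(a: float, b: float):
        return a / b if b != 0 else None

    out: dict[str, Any] = {"a": report_a.get("config", {}).get("label"),
                           "b": report_b.get("config", {}).get("label")}
    out["band_power_ratio"] = {
        k: _ratio(float(np.mean(report_a["band_power"][k])),
                  float(np.mean(report_b["band_power"][k])))
        for k in report_a["band_power"]}
    out["MIn_normalized_diff"] = (report_a["pac"]["MIn_normalized"]
                                  - report_b["pac"]["MIn_normalized"])
    for key in ("epileptiform", "ripples", "fast_ripples"):
        if key in report_a and key in report_b:
            out[f"{key}_rate_diff_per_min"] = (
                report_a[key]["event_rate_per_min"]
                - report_b[key]["event_rate_per_min"])
    if "ripples" in report_a and "ripples" in report_b:
        fa = report_a["ripples"]["mean_intra_freq_hz"]
        fb = report_b["ripples"]["mean_intra_freq_hz"]
        out["ripple_intra_freq_diff_hz"] = (
            fa - fb if fa is not None and fb is not None else None)
    return out
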