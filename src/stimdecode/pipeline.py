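"""End-to-end orchestration: simulate -> preprocess -> spectra -> decode ->
group statistics -> source reconstruction -> phase coupling.

These functions are the library's high-level surface; the command-line
interface is a thin wrapper around :func:`run_all`.  Seeds for simulation,
epoch shuffling, cross-validation folds and permutation tests are kept
separate and all recorded in the result manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .classify import ScoreMap, classify_all, pool_diff_features
from .coupling import PLV_CHANNELS, compare_plv, delta_plv
from .exceptions import ChannelError
from .group_stats import (ClusterResult, chance_test, cluster_permutation,
                          kruskal_wallis_roi, mean_power_contrast)
from .preprocess import preprocess_recording
from .source import lcmv_filters, roi_classify, source_band_power
from .spectral import BANDS, band_average, morlet_power, segment_average
from .synth import PHASES, PROTOCOLS, SimulatedStudy, StudyConfig, simulate_study

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def subject_features(study: SimulatedStudy, subject: str, condition: str,
                     freqs) -> dict[str, tuple]:
    """Segment-averaged spectral features per protocol and phase.

    Returns {protocol: (PRE SpectralFeatures, POST SpectralFeatures)} with
    power of shape (epochs, channels, freqs, 8 segments).
    """
    out = {}
    for proto in PROTOCOLS:
        pair = []
        for phase in PHASES:
            rec = study.recording(subject, proto, phase, condition)
            eps = preprocess_recording(rec, condition, phase=phase,
                                       protocol=proto, subject=subject).clean()
            sf = morlet_power(eps, freqs=freqs)
            pair.append(segment_average(sf))
        out[proto] = tuple(pair)
    return out


# ---------------------------------------------------------------------------
# Sensor-space decoding and statistics
# ---------------------------------------------------------------------------

def run_sensor_decoding(study: SimulatedStudy, condition: str = "task",
                        freqs=None, k: int = 10, shuffle_seed: int = 0,
                        cv_seed: int = 0,
                        features: dict | None = None) -> ScoreMap:
    """Per-channel, per-frequency protocol decoding for every subject."""
    if freqs is None:
        freqs = np.arange(4.0, 50.0)
    freqs = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(shuffle_seed)
    diff_sets = {}
    for subject in study.subjects:
        feats = (features or {}).get(subject) or subject_features(
            study, subject, condition, freqs)
        diff_sets[subject] = pool_diff_features(feats, seed=rng.integers(2**31))
    return classify_all(diff_sets, k=k, seed=cv_seed)


def run_cluster_test(scores: ScoreMap, study: SimulatedStudy,
                     band: str = "alpha", n_rand: int = 1000,
                     seed: int = 0) -> ClusterResult:
    """Cluster permutation test on band-averaged per-class F1 maps."""
    band_f1 = scores.band_f1(band)  # subjects x classes x channels
    return cluster_permutation(band_f1, study.montage.adjacency,
                               n_rand=n_rand, seed=seed,
                               channel_names=scores.channel_names)


def run_power_contrast(study: SimulatedStudy, condition: str = "task",
                       band: str = "alpha", n_rand: int = 1000, seed: int = 0,
                       features: dict | None = None) -> ClusterResult:
    """Cluster test on trial-averaged POST-PRE band power (the traditional
    univariate contrast, for comparison with the decoding pipeline)."""
    bdef = BANDS[band]
    freqs = np.arange(float(bdef.f_lo), float(bdef.f_hi) + 1)
    deltas = []
    for subject in study.subjects:
        feats = (features or {}).get(subject) or subject_features(
            study, subject, condition, freqs)
        row = []
        for proto in PROTOCOLS:
            pre, post = feats[proto]
            vals = []
            for sf in (pre, post):
                p = band_average(sf.power, sf.freqs, bdef, axis=2)
                vals.append(p.mean(axis=(0, 2)))  # trials & segments -> channel
            row.append(vals[1] - vals[0])
        deltas.append(np.stack(row))
    delta = np.stack(deltas)  # subjects x classes x channels
    ref = features or {study.subjects[0]: subject_features(
        study, study.subjects[0], condition, freqs)}
    channel_names = next(iter(ref.values()))[PROTOCOLS[0]][0].channel_names
    return mean_power_contrast(delta, study.montage.adjacency, n_rand=n_rand,
                               seed=seed, channel_names=channel_names)


# ---------------------------------------------------------------------------
# Source-space analysis
# ---------------------------------------------------------------------------

def run_source_analysis(study: SimulatedStudy, condition: str = "task",
                        band: str = "alpha", reg: float = 0.05, k: int = 10,
                        seed: int = 0, segments: int = 8):
    """LCMV + per-grid-point decoding + ROI statistics.

    Per subject and protocol, one spatial filter is computed from the
    band-passed sensor covariance pooled across PRE and POST trials; source
    band power is segmented into classifier features; decoding mirrors the
    sensor pipeline; ROI-averaged F1 feeds the chance-level and
    Kruskal-Wallis tests.
    """
    bdef = BANDS[band]
    rng = np.random.default_rng(seed)
    model = study.forward
    feats: dict = {}
    window = (0.0, 0.4)
    for subject in study.subjects:
        feats[subject] = {}
        for proto in PROTOCOLS:
            phase_eps = {}
            for phase in PHASES:
                rec = study.recording(subject, proto, phase, condition)
                eps = preprocess_recording(rec, condition, phase=phase,
                                           protocol=proto,
                                           subject=subject).clean()
                phase_eps[phase] = eps
            lf = model.leadfield_for(phase_eps["PRE"].channel_names,
                                     reference="common_average")
            from .spectral import band_filter
            rate = phase_eps["PRE"].rate
            pooled = np.concatenate([phase_eps[p].data for p in PHASES])
            pooled_bp = band_filter(pooled, rate, bdef)
            flat = pooled_bp.transpose(1, 0, 2).reshape(pooled_bp.shape[1], -1)
            cov = np.cov(flat)
            filters = lcmv_filters(cov, lf, reg=reg)
            n_pre = len(phase_eps["PRE"].data)
            slices = {"PRE": pooled_bp[:n_pre], "POST": pooled_bp[n_pre:]}
            pair = []
            for phase in PHASES:
                eps = phase_eps[phase]
                sp = source_band_power(slices[phase], rate, filters, bdef,
                                       window=window,
                                       t0_offset=eps.t0_offset,
                                       segments=segments, prefiltered=True)
                pair.append(sp)
            feats[subject][proto] = tuple(pair)
    point_f1, roi_f1, subjects, classes = roi_classify(
        feats, model, k=k, seed=rng.integers(2**31))
    rois = sorted(roi_f1)
    roi_macro = np.stack([roi_f1[r].mean(axis=1) for r in rois], axis=1)
    chance = chance_test(roi_macro, labels=rois)
    kw = kruskal_wallis_roi({r: roi_f1[r] for r in rois})
    return {"point_f1": point_f1, "roi_f1": roi_f1, "subjects": subjects,
            "classes": classes, "chance": chance, "kruskal": kw}


# ---------------------------------------------------------------------------
# Phase coupling
# ---------------------------------------------------------------------------

def run_plv_analysis(study: SimulatedStudy, condition: str = "task",
                     channels=PLV_CHANNELS, ratio=(1, 1)):
    """POST-PRE theta-alpha PLV per subject/protocol at the motor channels."""
    for ch in channels:
        if ch not in study.montage.scalp_names:
            raise ChannelError(f"PLV channel {ch} not in montage")
    dplv = np.zeros((study.n_subjects, len(PROTOCOLS), len(channels)))
    for si, subject in enumerate(study.subjects):
        for pi, proto in enumerate(PROTOCOLS):
            eps = {}
            for phase in PHASES:
                rec = study.recording(subject, proto, phase, condition)
                eps[phase] = preprocess_recording(
                    rec, condition, phase=phase, protocol=proto,
                    subject=subject).clean()
            for ci, ch in enumerate(channels):
                idx = eps["PRE"].channel_names.index(ch)
                dplv[si, pi, ci] = delta_plv(
                    eps["PRE"].data[:, idx, :], eps["POST"].data[:, idx, :],
                    eps["PRE"].rate, ratio=ratio)
    stats = compare_plv(dplv, PROTOCOLS, channels)
    return {"dplv": dplv, "stats": stats, "channels": list(channels)}


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration for a full run; defaults mirror the recorded study."""

    out_dir: str = "results"
    n_subjects: int = 24
    simulate: bool = True
    study: StudyConfig = field(default_factory=StudyConfig)
    condition: str = "task"
    band: tuple[float, float] = (1.0, 49.0)
    reject_uv: float = 70.0
    freq_range: tuple[float, float] = (4.0, 49.0)
    k_folds: int = 10
    n_randomizations: int = 1000
    chance_level: float = 1.0 / 3.0
    sim_seed: int = 0
    shuffle_seed: int = 1
    cv_seed: int = 2
    perm_seed: int = 3

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write results + manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        study = simulate_study(config.n_subjects, config.study,
                               seed=config.sim_seed)
        stage = "decode"
        freqs = np.arange(config.freq_range[0], config.freq_range[1] + 1)
        scores = run_sensor_decoding(study, condition=config.condition,
                                     freqs=freqs, k=config.k_folds,
                                     shuffle_seed=config.shuffle_seed,
                                     cv_seed=config.cv_seed)
        stage = "group-stats"
        clusters = {}
        for band in ("theta", "alpha"):
            if BANDS[band].f_lo >= freqs[0] and BANDS[band].f_hi <= freqs[-1]:
                clusters[band] = run_cluster_test(
                    scores, study, band=band,
                    n_rand=config.n_randomizations, seed=config.perm_seed)
        stage = "band-correlation"
        correlations = {}
        if all(BANDS[b].f_lo >= freqs[0] and BANDS[b].f_hi <= freqs[-1]
               for b in ("theta", "alpha")):
            from .group_stats import band_correlation, compare_correlations

            site = [c for c in ("FC3", "CP3")
                    if c in scores.channel_names]
            idx = [scores.channel_names.index(c) for c in site]
            for ci, proto in enumerate(scores.classes):
                th = scores.band_f1("theta")[:, ci, idx].mean(axis=1)
                al = scores.band_f1("alpha")[:, ci, idx].mean(axis=1)
                r, p = band_correlation(th, al)
                correlations[proto] = {"r": r, "p": p}
            n = len(scores.subjects)
            z, pz = compare_correlations(
                correlations["lMC"]["r"], n, correlations["sham"]["r"], n)
            correlations["lMC_vs_sham"] = {"Z": z, "p": pz}
        stage = "source"
        source = run_source_analysis(study, condition=config.condition,
                                     k=config.k_folds, seed=config.perm_seed)
        stage = "plv"
        plv_res = run_plv_analysis(study, condition=config.condition)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    results = {
        "config": dataclasses.asdict(config),
        "version": _pkg_version,
        "clusters": {
            b: {
                "mc_p": c.mc_p.tolist(),
                "channels": [[c.channel_names[i] for i in cl]
                             for cl in c.clusters],
                "threshold": c.threshold,
            } for b, c in clusters.items()
        },
        "band_correlations": correlations,
        "source_chance": source["chance"].to_dict(orient="records"),
        "source_kruskal": source["kruskal"].to_dict(orient="records"),
        "plv": plv_res["stats"]["channels"],
        "mean_band_f1": {
            b: float(scores.band_f1(b, per_class=False).mean())
            for b in ("theta", "alpha")
            if BANDS[b].f_lo >= freqs[0] and BANDS[b].f_hi <= freqs[-1]
        },
    }
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, default=str)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"version": _pkg_version,
                   "seeds": {"simulation": config.sim_seed,
                             "shuffle": config.shuffle_seed,
                             "cv": config.cv_seed,
                             "permutation": config.perm_seed},
                   "config": dataclasses.asdict(config)},
                  fh, indent=1, default=str)
    np.save(out / "band_f1.npy", scores.band_f1("alpha"))
    return results
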