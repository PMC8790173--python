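"""Synthetic multi-subject EEG studies with known planted effects.

Each study emulates the recorded design: per subject, three stimulation
protocols (lMC / rCB / sham), each with PRE and POST recordings of a
stimulus-locked task plus eyes-open/eyes-closed rest.  Sensor signals are a
sum of leadfield-projected band-limited oscillatory sources (amplitude-
modulated sinusoids, random phase per epoch, +-1 Hz frequency jitter),
1/f background noise and white sensor noise, recorded against the online
reference CPz.  The planted aftereffect is a focal alpha-band power change
at the stimulation site (FC3/CP3) present only in POST recordings of the
lMC protocol; the rCB protocol's "effect" is a latent deep source whose
scalp gain is zero by construction, mirroring the absence of cerebellar
electrode coverage.  Recordings are generated lazily and deterministically
from the study seed, so a study is bit-reproducible without holding
gigabytes in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal.windows import tukey

from .exceptions import ConfigurationError
from .io import write_edf, write_sidecar
from .montage import Montage, make_montage
from .preprocess import Recording
from .source import SourceModel, build_forward

PROTOCOLS = ("lMC", "rCB", "sham")
PHASES = ("PRE", "POST")


@dataclass(frozen=True)
class OscSource:
    """One oscillatory source of the generator.

    ``anchor`` is either a channel name (the source sits under that
    electrode) or a unit direction from the sphere origin.  ``amp`` is the
    nominal peak scalp amplitude in uV at the most sensitive electrode;
    ``post_power_factor`` maps protocol -> multiplicative power change
    applied in the POST phase only.  ``scalp_gain`` scales the projected
    pattern (0 makes the source latent / invisible at the scalp).
    """

    name: str
    anchor: object
    freq: float
    radial_frac: float = 0.75
    bw: float = 1.0
    amp: float = 6.0
    scalp_gain: float = 1.0
    orientation: str = "radial"  # 'radial' peaks under the anchor electrode
    post_power_factor: dict = field(default_factory=dict)
    locked_to: str | None = None
    lock_when: tuple = ()
    lock_lag: float = 0.0


@dataclass
class GroundTruth:
    """The planted effect a downstream analysis should recover."""

    effect_channels: tuple = ("FC3", "CP3")
    effect_band: tuple = (9.0, 13.0)
    effect_sign: int = -1
    effect_size: float = 0.3
    source_locations: np.ndarray = field(default_factory=lambda: np.array([], int))
    seed: int = 0

    def validate(self, montage: Montage) -> None:
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        lo, hi = self.effect_band
        if not 1 <= lo <= hi <= 49:
            raise ConfigurationError("effect_band must lie within [1, 49] Hz")
        missing = set(self.effect_channels) - set(montage.names)
        if missing:
            raise ConfigurationError(f"effect channels not in montage: {missing}")


@dataclass
class StudyConfig:
    """Generator settings; the defaults emulate the recorded study.

    24 subjects, 64 channels at 512 Hz, ~80 task epochs and 170 4-s rest
    epochs per phase, a 30% alpha power decrease at FC3/CP3 in lMC-POST.
    Tests use reduced channel counts, epoch counts and 128 Hz for speed.
    """

    n_channels: int = 64
    rate: float = 512.0
    n_task_epochs: int = 80
    rest_duration: float = 680.0   # seconds; 4-s epochs -> 170 per phase
    conditions: tuple = ("task", "RSEO", "RSEC")
    trial_period: float = 3.5
    event_offset: float = 1.25     # stimulus time inside each trial period
    pad: float = 1.0

    effect_size: float = 0.3
    effect_sign: int = -1
    effect_freq: float = 10.0
    effect_band: tuple = (9.0, 13.0)
    effect_channels: tuple = ("FC3", "CP3")

    osc_amp: float = 3.6           # uV peak scalp amplitude of the motor source
    pink_sigma: float = 4.0        # uV, 1/f background
    white_sigma: float = 1.0       # uV, sensor noise
    noise_slope: float = 1.0
    subject_sigma: float = 0.2     # log-normal oscillation amplitude factor
    subject_gain_sigma: float = 0.6  # log-normal whole-recording gain
    effect_responder_sigma: float = 0.75  # per-subject effect modulation
    epoch_amp_sigma: float = 0.1   # log-normal per-epoch amplitude

    grid_spacing: float = 0.012
    couple_theta_alpha: tuple = ()  # e.g. (("lMC", "POST"),)
    sources: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_task_epochs <= 0 or self.rest_duration <= 0:
            raise ConfigurationError("epoch counts must be positive")
        if min(self.pink_sigma, self.white_sigma) <= 0 or self.osc_amp <= 0:
            raise ConfigurationError("noise and source amplitudes must be > 0")
        if self.event_offset < 1.0 or \
                self.trial_period - self.event_offset < 2.0:
            raise ConfigurationError(
                "event_offset must leave room for the -1..+2 s task epoch")

    def build_sources(self, montage: Montage) -> list[OscSource]:
        if self.sources is not None:
            return list(self.sources)
        delta = self.effect_sign * self.effect_size
        # one dipole under each stimulation electrode; post_power_factor
        # holds the *mean* power change, modulated per subject by the
        # responder factor at synthesis time
        srcs = [OscSource(
            name=f"motor_alpha_{ch}", anchor=ch,
            freq=self.effect_freq, amp=self.osc_amp,
            post_power_factor={"lMC": 1.0 + delta})
            for ch in self.effect_channels]
        if "Oz" in montage.names:
            srcs.append(OscSource(name="occipital_alpha", anchor="Oz",
                                  freq=10.0, amp=0.7 * self.osc_amp))
        if "Fz" in montage.names:
            srcs.append(OscSource(name="frontal_theta", anchor="Fz",
                                  freq=6.0, amp=0.6 * self.osc_amp))
        srcs.append(OscSource(
            name="cerebellar_latent",
            anchor=np.array([0.0, -0.6, -0.8]) / np.hypot(0.6, 0.8),
            freq=self.effect_freq, amp=self.osc_amp, scalp_gain=0.0,
            orientation="max_gain", post_power_factor={"rCB": 1.0 + delta}))
        if self.couple_theta_alpha:
            ref = f"motor_alpha_{self.effect_channels[0]}"
            srcs.append(OscSource(
                name="motor_theta", anchor=self.effect_channels[0], freq=6.0,
                amp=self.osc_amp, locked_to=ref,
                lock_when=tuple(self.couple_theta_alpha)))
        return srcs


def _anchor_direction(source: OscSource, montage: Montage) -> np.ndarray:
    if isinstance(source.anchor, str):
        if source.anchor == "__effect_site__":
            # midpoint of the stimulation electrodes, i.e. roughly under C3
            d = (montage.positions[montage.index("FC3")]
                 + montage.positions[montage.index("CP3")])
        else:
            d = montage.positions[montage.index(source.anchor)].copy()
        return d / np.linalg.norm(d)
    d = np.asarray(source.anchor, dtype=float)
    return d / np.linalg.norm(d)


@dataclass
class SimulatedStudy:
    """A lazily-generated multi-subject synthetic study."""

    montage: Montage
    truth: GroundTruth
    forward: SourceModel
    config: StudyConfig
    seed: int
    n_subjects: int
    subject_factors: np.ndarray   # oscillation-specific amplitude factors
    subject_gains: np.ndarray     # whole-recording gains (head/skull scale)
    subject_response: np.ndarray  # per-subject effect (responder) factors
    _patterns: dict = field(default_factory=dict, repr=False)

    @property
    def subjects(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_subjects)]

    # -- deterministic per-recording RNG --------------------------------
    def _rng(self, si: int, protocol: str, phase: str, condition: str):
        key = (self.seed, si, PROTOCOLS.index(protocol),
               PHASES.index(phase), list(self.config.conditions).index(condition))
        return np.random.default_rng(np.random.SeedSequence(key))

    def source_pattern(self, source: OscSource) -> tuple[int, np.ndarray]:
        """Grid index and per-channel scalp pattern of a source.

        The pattern is the forward solution at the nearest grid point, along
        the orientation of maximum scalp gain, re-referenced to the online
        reference CPz and normalised to unit peak absolute amplitude.
        """
        if source.name in self._patterns:
            return self._patterns[source.name]
        direction = _anchor_direction(source, self.montage)
        pos = (np.asarray(self.montage.origin)
               + source.radial_frac * self.montage.head_radius * direction)
        gi = int(np.argmin(np.linalg.norm(self.forward.grid - pos, axis=1)))
        lf = self.forward.leadfield[gi]  # n_scalp x 3
        if source.orientation == "radial":
            u = direction
        else:  # orientation of maximum scalp gain
            _, _, vt = np.linalg.svd(lf, full_matrices=False)
            u = vt[0]
            if u[np.argmax(np.abs(u))] < 0:
                u = -u
        scalp = lf @ u
        # expand to the full montage (mastoids get zero pick-up here)
        full = np.zeros(len(self.montage.names))
        for ci, name in enumerate(self.forward.channel_names):
            full[self.montage.index(name)] = scalp[ci]
        full -= full[self.montage.index("CPz")]
        peak = np.max(np.abs(full))
        pattern = source.scalp_gain * full / peak if peak > 0 else full * 0.0
        self._patterns[source.name] = (gi, pattern)
        return gi, pattern

    # -- recording synthesis --------------------------------------------
    def recording(self, subject: str, protocol: str, phase: str,
                  condition: str = "task") -> Recording:
        cfg = self.config
        si = self.subjects.index(subject)
        rng = self._rng(si, protocol, phase, condition)
        rate = cfg.rate
        if condition == "task":
            n_ep, seg = cfg.n_task_epochs, cfg.trial_period
        else:
            n_ep, seg = int(cfg.rest_duration // 4.0), 4.0
        n_samp = int(round(rate * (n_ep * seg + cfg.pad)))
        seg_n = int(round(rate * seg))
        t_seg = np.arange(seg_n) / rate
        env = tukey(seg_n, alpha=min(0.2, 0.1 / max(seg / 3.5, 1e-9)))

        sources = cfg.build_sources(self.montage)
        by_name = {s.name: s for s in sources}
        # draw all per-epoch parameters first so locking can override them
        params = {}
        for s in sources:
            f = s.freq + (rng.uniform(-s.bw, s.bw, n_ep) if s.bw > 0 else 0.0)
            phi = rng.uniform(0, 2 * np.pi, n_ep)
            a = rng.lognormal(0.0, cfg.epoch_amp_sigma, n_ep)
            params[s.name] = [np.broadcast_to(f, (n_ep,)).copy(), phi, a]
        for s in sources:
            if s.locked_to and (protocol, phase) in s.lock_when:
                ref = by_name[s.locked_to]
                params[s.name][0][:] = s.freq
                params[ref.name][0][:] = ref.freq
                params[s.name][1] = params[ref.name][1] + s.lock_lag

        data = np.zeros((len(self.montage.names), n_samp))
        subj_amp = self.subject_factors[si]
        for s in sources:
            _, pattern = self.source_pattern(s)
            if not np.any(pattern):
                continue
            factor = 1.0
            if phase == "POST" and protocol in s.post_power_factor:
                # per-subject responder modulation of the mean power change:
                # aftereffects vary in magnitude (and occasionally sign)
                # across individuals
                delta = s.post_power_factor[protocol] - 1.0
                pf = 1.0 + delta * self.subject_response[si]
                factor = np.sqrt(max(pf, 0.05))
            f, phi, a = params[s.name]
            wave = np.zeros(n_samp)
            for k in range(n_ep):
                i0 = int(round(k * seg * rate))
                wave[i0:i0 + seg_n] += (a[k] * env
                                        * np.sin(2 * np.pi * f[k] * t_seg + phi[k]))
            data += np.outer(pattern, s.amp * subj_amp * factor * wave)

        data += self._background(rng, data.shape)
        data += cfg.white_sigma * rng.standard_normal(data.shape)
        # whole-recording subject gain: head geometry / skull conductivity /
        # electrode impedance scale signal and noise together
        data *= self.subject_gains[si]
        # online reference: recorded against CPz
        cpz = self.montage.index("CPz")
        data -= data[cpz]
        data[cpz] = 0.0

        if condition == "task":
            events = [(int(round((k * seg + cfg.event_offset) * rate)),
                       "task_stimulus") for k in range(n_ep)]
        else:
            events = [(0, "rest_start")]
        return Recording(data=data, rate=rate,
                         channel_names=list(self.montage.names),
                         events=events)

    def _background(self, rng, shape) -> np.ndarray:
        """1/f (pink) noise, flat below 1 Hz, per channel."""
        cfg = self.config
        n_ch, n = shape
        white = rng.standard_normal((n_ch, n))
        spec = np.fft.rfft(white, axis=1)
        freqs = np.fft.rfftfreq(n, 1.0 / cfg.rate)
        gain = np.maximum(freqs, 1.0) ** (-cfg.noise_slope / 2.0)
        gain[0] = 0.0
        pink = np.fft.irfft(spec * gain, n=n, axis=1)
        pink *= cfg.pink_sigma / pink.std(axis=1, keepdims=True)
        return pink

    # -- export ----------------------------------------------------------
    def write_edf(self, directory) -> None:
        """One EDF + JSON sidecar per recording, plus the montage TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.montage.to_tsv(directory / "montage.tsv")
        for subj in self.subjects:
            for proto in PROTOCOLS:
                for phase in PHASES:
                    for cond in self.config.conditions:
                        rec = self.recording(subj, proto, phase, cond)
                        stem = f"{subj}_{proto}_{phase}_{cond}"
                        write_edf(directory / f"{stem}.edf", rec.data,
                                  rec.rate, rec.channel_names)
                        write_sidecar(
                            directory / f"{stem}.edf.json",
                            events=rec.events, n_samples=rec.data.shape[1],
                            rate=rec.rate,
                            extra={"seed": self.seed, "subject": subj,
                                   "protocol": proto, "phase": phase,
                                   "condition": cond})


def simulate_study(n_subjects: int = 24, config: StudyConfig | None = None,
                   seed: int = 0) -> SimulatedStudy:
    """Build a deterministic synthetic study with a known planted effect."""
    if n_subjects <= 0:
        raise ConfigurationError("n_subjects must be positive")
    cfg = config or StudyConfig()
    montage = make_montage(cfg.n_channels)
    forward = build_forward(montage, grid_spacing=cfg.grid_spacing)
    truth = GroundTruth(effect_channels=tuple(cfg.effect_channels),
                        effect_band=tuple(cfg.effect_band),
                        effect_sign=cfg.effect_sign,
                        effect_size=cfg.effect_size, seed=seed)
    truth.validate(montage)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    factors = rng.lognormal(0.0, cfg.subject_sigma, n_subjects)
    # truncate the gain tail: a recording whose overall amplitude exceeded
    # the artifact threshold everywhere would be re-prepped or excluded in
    # practice, not analysed
    gains = np.clip(rng.lognormal(0.0, cfg.subject_gain_sigma, n_subjects),
                    0.4, 2.5)
    response = rng.normal(1.0, cfg.effect_responder_sigma, n_subjects)
    study = SimulatedStudy(montage=montage, truth=truth, forward=forward,
                           config=cfg, seed=seed, n_subjects=n_subjects,
                           subject_factors=factors, subject_gains=gains,
                           subject_response=response)
    locs = []
    for s in cfg.build_sources(montage):
        gi, _ = study.source_pattern(s)
        if s.scalp_gain > 0:
            locs.append(gi)
    truth.source_locations = np.asarray(locs, dtype=int)
    return study


def inject_artifacts(recording: Recording, rate_per_min: float,
                     amplitude: float, seed: int = 0,
                     times: list[float] | None = None,
                     width: float = 0.1) -> Recording:
    """Add high-amplitude transients (rejectable artifacts) to a recording.

    Transients are raised-cosine bumps of the given peak ``amplitude`` (uV)
    and ``width`` (s) on a random channel; their onset times are logged in
    ``artifact_times``.  ``rate_per_min=0`` (and no explicit times) returns
    an unchanged copy.
    """
    out = recording.copy()
    dur_min = recording.data.shape[1] / recording.rate / 60.0
    rng = np.random.default_rng(seed)
    if times is None:
        n = int(round(rate_per_min * dur_min))
        if n == 0:
            return out
        tmax = recording.data.shape[1] / recording.rate - width
        times = np.sort(rng.uniform(0, tmax, n)).tolist()
    w = int(round(width * recording.rate))
    bump = amplitude * np.hanning(w)
    for t in times:
        i0 = int(round(t * recording.rate))
        i1 = min(i0 + w, out.data.shape[1])
        ch = rng.integers(len(out.channel_names))
        out.data[ch, i0:i1] += bump[: i1 - i0]
        out.artifact_times.append(float(t))
    return out
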