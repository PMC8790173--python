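"""Continuous-EEG preprocessing: filter, re-reference, epoch, reject.

The pipeline order is fixed: band-pass (1-49 Hz) -> mastoid re-reference ->
(optional artifact-removal hook, a stand-in for ICA blink removal) ->
epoching -> +-70 uV threshold rejection -> common-average re-reference of the
retained scalp channels.  Every operation returns a new container; inputs are
never mutated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ChannelError, ConfigurationError
from .montage import MASTOIDS

logger = logging.getLogger(__name__)

#: Task epochs span -1..+2 s around stimulus onset.
TASK_WINDOW = (-1.0, 2.0)
#: Rest epochs are non-overlapping 4-s windows.
REST_EPOCH_LEN = 4.0
#: Default rejection threshold in uV.
REJECT_UV = 70.0


@dataclass
class Recording:
    """A continuous multichannel recording in microvolts."""

    data: np.ndarray  # channels x samples
    rate: float
    channel_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    artifact_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ConfigurationError("sampling rate must be positive")
        n = self.data.shape[1]
        for s, _ in self.events:
            if not 0 <= s < n:
                raise ConfigurationError(f"event sample {s} outside recording")

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channel_names=list(self.channel_names),
            events=list(self.events),
            artifact_times=list(self.artifact_times),
        )


@dataclass
class EpochSet:
    """A rectangular stack of fixed-length epochs with per-epoch metadata.

    ``meta`` carries one row per epoch with columns ``phase`` (PRE/POST),
    ``protocol`` (lMC/rCB/sham), ``condition`` (task/RSEO/RSEC) and
    ``subject``.  ``rejected_mask`` marks epochs excluded from every
    downstream count; :meth:`clean` drops them.
    """

    data: np.ndarray  # epochs x channels x samples
    rate: float
    t0_offset: float
    channel_names: list[str]
    meta: pd.DataFrame
    rejected_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(len(self.data), dtype=bool)

    @property
    def n_epochs(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_kept(self) -> int:
        return int((~self.rejected_mask).sum())

    def clean(self) -> "EpochSet":
        """Return a new EpochSet containing only non-rejected epochs."""
        keep = ~self.rejected_mask
        return EpochSet(
            data=self.data[keep],
            rate=self.rate,
            t0_offset=self.t0_offset,
            channel_names=list(self.channel_names),
            meta=self.meta.loc[keep].reset_index(drop=True),
            rejected_mask=np.zeros(int(keep.sum()), dtype=bool),
        )

    def times(self) -> np.ndarray:
        """Per-sample time axis in seconds relative to the epoch anchor."""
        return np.arange(self.data.shape[2]) / self.rate - self.t0_offset


def bandpass(recording: Recording, f_lo: float, f_hi: float,
             transition: float = 1.0) -> Recording:
    """Zero-phase FIR band-pass with narrow (default 1 Hz) transition bands.

    The narrow upper transition is what lets a 1-49 Hz band remove 50-Hz line
    noise; attenuation in the stopband exceeds 50 dB (Hamming window design).
    """
    if not 0 < f_lo < f_hi < recording.rate / 2:
        raise ConfigurationError(
            f"invalid band [{f_lo}, {f_hi}] Hz at rate {recording.rate}"
        )
    import mne

    filtered = mne.filter.filter_data(
        recording.data, recording.rate, l_freq=f_lo, h_freq=f_hi,
        l_trans_bandwidth=min(transition, f_lo),
        h_trans_bandwidth=transition,
        phase="zero", fir_design="firwin", verbose="ERROR",
    )
    out = recording.copy()
    out.data = filtered
    return out


def rereference(recording: Recording, scheme: str = "mastoid_average",
                keep_mastoids: bool = False) -> Recording:
    """Re-reference a recording.

    ``mastoid_average`` subtracts (M1+M2)/2 from every channel, which also
    re-calculates the online-reference channel CPz as a proper data channel;
    the mastoids are then dropped unless ``keep_mastoids``.  ``common_average``
    subtracts the instantaneous mean over the present channels.
    """
    out = recording.copy()
    if scheme == "mastoid_average":
        for m in MASTOIDS:
            if m not in recording.channel_names:
                raise ChannelError(f"mastoid channel {m} missing")
        idx = [recording.channel_names.index(m) for m in MASTOIDS]
        ref = recording.data[idx].mean(axis=0)
        out.data = recording.data - ref
        if not keep_mastoids:
            keep = [i for i in range(len(out.channel_names)) if i not in idx]
            out.data = out.data[keep]
            out.channel_names = [out.channel_names[i] for i in keep]
    elif scheme == "common_average":
        out.data = recording.data - recording.data.mean(axis=0)
    else:
        raise ConfigurationError(f"unknown re-reference scheme {scheme!r}")
    return out


def common_average_epochs(epochs: EpochSet) -> EpochSet:
    """Common-average re-reference applied per sample across channels."""
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data, meta=epochs.meta.copy(),
                   rejected_mask=epochs.rejected_mask.copy())


def epoch(recording: Recording, condition: str, *, phase: str = "",
          protocol: str = "", subject: str = "") -> EpochSet:
    """Cut a recording into epochs.

    Task data: one 3-s epoch per ``task_stimulus`` event, spanning -1..+2 s
    around stimulus onset.  Rest data (RSEO/RSEC): consecutive non-overlapping
    4-s windows from the ``rest_start`` event to the end of the recording.
    Epochs that would extend past the recording bounds are dropped with a
    logged warning.
    """
    n_samp = recording.data.shape[1]
    rate = recording.rate
    windows: list[tuple[int, int]] = []
    if condition == "task":
        events = [s for s, k in recording.events if k == "task_stimulus"]
        if not events:
            raise ConfigurationError("task epoching requires stimulus events")
        pre = int(round(-TASK_WINDOW[0] * rate))
        post = int(round(TASK_WINDOW[1] * rate))
        n_dropped = 0
        for s in events:
            if s - pre < 0 or s + post > n_samp:
                n_dropped += 1
                continue
            windows.append((s - pre, s + post))
        if n_dropped:
            logger.warning("dropped %d out-of-bounds task epochs", n_dropped)
        t0_offset = -TASK_WINDOW[0]
    else:
        starts = [s for s, k in recording.events if k == "rest_start"]
        if not starts:
            raise ConfigurationError("rest epoching requires a rest_start event")
        length = int(round(REST_EPOCH_LEN * rate))
        s = starts[0]
        while s + length <= n_samp:
            windows.append((s, s + length))
            s += length
        t0_offset = 0.0
    data = np.stack([recording.data[:, a:b] for a, b in windows])
    meta = pd.DataFrame(
        {
            "phase": phase,
            "protocol": protocol,
            "condition": condition,
            "subject": subject,
        },
        index=range(len(windows)),
    )
    return EpochSet(data=data, rate=rate, t0_offset=t0_offset,
                    channel_names=list(recording.channel_names), meta=meta)


def reject_epochs(epochs: EpochSet, lo: float = -REJECT_UV,
                  hi: float = REJECT_UV) -> EpochSet:
    """Mark epochs with any sample outside (lo, hi) uV as rejected."""
    if lo >= hi:
        raise ConfigurationError("rejection threshold requires lo < hi")
    bad = ((epochs.data < lo) | (epochs.data > hi)).any(axis=(1, 2))
    out = replace(epochs, data=epochs.data.copy(), meta=epochs.meta.copy(),
                  rejected_mask=epochs.rejected_mask | bad)
    logger.info("rejected %d/%d epochs at [%g, %g] uV",
                int(bad.sum()), epochs.n_epochs, lo, hi)
    return out


def preprocess_recording(recording: Recording, condition: str, *,
                         band=(1.0, 49.0), reject_uv: float = REJECT_UV,
                         ica_hook=None, phase: str = "", protocol: str = "",
                         subject: str = "") -> EpochSet:
    """Full preprocessing chain for one recording.

    Order: band-pass -> mastoid re-reference (mastoids dropped) -> optional
    ``ica_hook(recording) -> recording`` (blink-removal stand-in; skipped and
    logged when None) -> epoch -> threshold rejection -> common-average.
    """
    rec = bandpass(recording, *band)
    rec = rereference(rec, "mastoid_average")
    if ica_hook is not None:
        rec = ica_hook(rec)
    else:
        logger.info("ICA stage skipped (no hook provided)")
    eps = epoch(rec, condition, phase=phase, protocol=protocol, subject=subject)
    eps = reject_epochs(eps, -reject_uv, reject_uv)
    return common_average_epochs(eps)
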