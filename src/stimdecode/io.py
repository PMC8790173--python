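"""File I/O: EDF continuous recordings, JSON sidecars, HDF5 epoch containers.

EDF reading goes through :func:`mne.io.read_raw_edf`.  Writing uses a minimal
EDF implementation (16-bit samples, one-second data records, fixed 0.1-uV
quantisation) because no EDF export backend is available; round-trips through
MNE's reader are exercised in the test suite.  Event markers, ground truth and
seeds travel in a JSON sidecar next to each EDF file.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

# physical range +-3276.7 uV against digital +-32767 -> 0.1 uV / bit
_PHYS_MAX = 3276.7
_DIG_MAX = 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} ({width})")
    return b + b" " * (width - len(b))


def write_edf(path, data: np.ndarray, rate: float, channel_names) -> None:
    """Write ``data`` (channels x samples, uV) as a plain EDF file.

    ``rate`` must be a whole number of samples per second; the final partial
    record is zero-padded (record the true sample count in a sidecar if it
    matters downstream).
    """
    if rate <= 0 or rate != int(rate):
        raise ValueError("EDF writer needs an integer sampling rate")
    rate = int(rate)
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length mismatch")
    n_rec = math.ceil(n_samp / rate)
    padded = np.zeros((n_ch, n_rec * rate))
    padded[:, :n_samp] = np.clip(data, -_PHYS_MAX, _PHYS_MAX)
    digital = np.round(padded / _PHYS_MAX * _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X X X X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (n_ch + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for name in channel_names:
            fh.write(_pad(f"EEG {name}", 16))
        for _ in channel_names:
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in channel_names:
            fh.write(_pad("uV", 8))
        for _ in channel_names:
            fh.write(_pad(f"{-_PHYS_MAX}", 8))
        for _ in channel_names:
            fh.write(_pad(f"{_PHYS_MAX}", 8))
        for _ in channel_names:
            # symmetric digital range so value = digital * 0.1 uV exactly
            fh.write(_pad(str(-_DIG_MAX), 8))
        for _ in channel_names:
            fh.write(_pad(str(_DIG_MAX), 8))
        for _ in channel_names:
            fh.write(_pad("BP 1-49 Hz", 80))
        for _ in channel_names:
            fh.write(_pad(str(rate), 8))
        for _ in channel_names:
            fh.write(_pad("", 32))
        # data records: record-major, channel blocks of `rate` samples
        for r in range(n_rec):
            fh.write(digital[:, r * rate:(r + 1) * rate].tobytes())


def read_edf(path, sidecar=None):
    """Read an EDF file (via MNE) back into a :class:`~stimdecode.preprocess.Recording`.

    If ``sidecar`` is None, ``<path>.json`` is used when present.  The sidecar
    restores event markers and the unpadded sample count.
    """
    import mne

    from .preprocess import Recording

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # MNE loads volts; we carry uV
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    rate = float(raw.info["sfreq"])
    events: list[tuple[int, str]] = []
    if sidecar is None:
        candidate = Path(str(path) + ".json")
        sidecar = candidate if candidate.exists() else None
    if sidecar is not None:
        with open(sidecar) as fh:
            meta = json.load(fh)
        events = [(int(s), str(k)) for s, k in meta.get("events", [])]
        n_samp = int(meta.get("n_samples", data.shape[1]))
        data = data[:, :n_samp]
    return Recording(data=data, rate=rate, channel_names=names, events=events)


def write_sidecar(path, *, events, n_samples, rate, extra=None) -> None:
    payload = {
        "events": [[int(s), str(k)] for s, k in events],
        "n_samples": int(n_samples),
        "rate": float(rate),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def save_epochs(path, epochs) -> None:
    """Persist an EpochSet to an HDF5 file (datasets: data/rate/meta/...)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.attrs["rate"] = epochs.rate
        f.attrs["t0_offset"] = epochs.t0_offset
        f.create_dataset("rejected_mask", data=epochs.rejected_mask)
        f.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype="S16"),
        )
        g = f.create_group("meta")
        for col in epochs.meta.columns:
            vals = epochs.meta[col].to_numpy()
            if vals.dtype.kind in "OU":
                vals = vals.astype("S32")
            g.create_dataset(col, data=vals)


def load_epochs(path):
    import h5py
    import pandas as pd

    from .preprocess import EpochSet

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        meta = pd.DataFrame(
            {
                col: [
                    v.decode() if isinstance(v, bytes) else v
                    for v in f["meta"][col][()]
                ]
                for col in f["meta"]
            }
        )
        return EpochSet(
            data=data,
            rate=float(f.attrs["rate"]),
            t0_offset=float(f.attrs["t0_offset"]),
            channel_names=[n.decode() for n in f["channel_names"][()]],
            meta=meta,
            rejected_mask=f["rejected_mask"][()].astype(bool),
        )
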