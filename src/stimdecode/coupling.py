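"""Theta-alpha phase coupling via the phase-locking value (PLV).

PLV_{theta,alpha}(t) = (1/N) | sum_trials exp(i [phi_theta(t) - phi_alpha(t)]) |

with N the number of trials and phi(t) the Hilbert phase of the band-limited
oscillation.  The phase difference is taken 1:1 between the two bands, as
printed; an optional n:m mode (n phi_theta - m phi_alpha, e.g. 2:1) is
available since a 1:1 difference between oscillators of different centre
frequency drifts unless they share a generator.  The reported scalar averages
the per-timepoint PLV over the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .exceptions import ConfigurationError, DegenerateDataError
from .group_stats import fdr, kruskal_wallis, wilcoxon_posthocs
from .spectral import BANDS, BandDefinition, band_filter

PLV_CHANNELS = ("FC3", "C3", "CP3")


def instantaneous_phase(signal: np.ndarray, rate: float | None = None,
                        band: BandDefinition | None = None,
                        prefiltered: bool = False) -> np.ndarray:
    """Hilbert phase (radians) of a band-limited signal, last axis = time."""
    x = np.asarray(signal, dtype=float)
    if not prefiltered:
        if rate is None or band is None:
            raise ConfigurationError("rate and band required unless prefiltered")
        x = band_filter(x, rate, band)
    return np.angle(hilbert(x, axis=-1))


@dataclass
class PLVResult:
    plv: float
    plv_t: np.ndarray       # per-timepoint PLV across trials
    n_trials: int
    band_pair: tuple[str, str]
    ratio: tuple[int, int]


def plv(epochs_data: np.ndarray, rate: float,
        bands: tuple[BandDefinition, BandDefinition] = (BANDS["theta"], BANDS["alpha"]),
        ratio: tuple[int, int] = (1, 1),
        edge: float = 0.5) -> PLVResult:
    """Phase-locking value between two bands of single-channel epochs.

    ``epochs_data``: (n_trials, n_samples) of one channel.  The PLV is
    computed per time point across trials and averaged over the window after
    discarding ``edge`` seconds at each end (Hilbert edge effects).
    ``ratio=(n, m)`` generalises the phase difference to n:m locking.
    """
    x = np.atleast_2d(np.asarray(epochs_data, dtype=float))
    n_trials = x.shape[0]
    if n_trials < 1:
        raise DegenerateDataError("PLV needs >= 1 trial")
    b1, b2 = bands
    ph1 = instantaneous_phase(x, rate, b1)
    ph2 = instantaneous_phase(x, rate, b2)
    n, m = ratio
    dphi = n * ph1 - m * ph2
    plv_t = np.abs(np.exp(1j * dphi).mean(axis=0))
    k = int(round(edge * rate))
    core = plv_t[k: len(plv_t) - k] if len(plv_t) > 2 * k else plv_t
    return PLVResult(plv=float(core.mean()), plv_t=plv_t, n_trials=n_trials,
                     band_pair=(b1.name, b2.name), ratio=(n, m))


def delta_plv(pre_epochs: np.ndarray, post_epochs: np.ndarray, rate: float,
              **kwargs) -> float:
    """POST - PRE phase-locking value for one channel."""
    return plv(post_epochs, rate, **kwargs).plv - plv(pre_epochs, rate, **kwargs).plv


def compare_plv(dplv: np.ndarray, class_names, channels=PLV_CHANNELS):
    """Kruskal-Wallis across protocols of per-subject POST-PRE PLV.

    ``dplv``: (n_subjects, n_classes, n_channels) of PLV changes at the
    tested channels (default FC3, C3, CP3).  FDR across the channel family;
    Wilcoxon signed-rank post-hocs per significant channel.  Returns a dict
    with per-channel H, raw and adjusted p, and post-hoc tables.
    """
    x = np.asarray(dplv, dtype=float)
    if x.ndim != 3 or x.shape[2] != len(channels):
        raise ConfigurationError("dplv must be (subjects, classes, channels)")
    if np.allclose(x.std(axis=0), 0):
        raise DegenerateDataError("PLV constant across subjects")
    rows = []
    for ci, ch in enumerate(channels):
        h, p = kruskal_wallis([x[:, c, ci] for c in range(x.shape[1])])
        rows.append({"channel": ch, "H": h, "p_raw": p})
    p_fdr = fdr(np.array([r["p_raw"] for r in rows]))
    posthocs = {}
    for ci, (row, q) in enumerate(zip(rows, p_fdr)):
        row["p_fdr"] = float(q)
        if q < 0.05:
            posthocs[row["channel"]] = wilcoxon_posthocs(
                x[:, :, ci], list(class_names)).table
    return {"channels": rows, "posthocs": posthocs}
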