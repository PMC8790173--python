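"""Electrode montage: names, unit-sphere positions, neighbour graph.

The montage follows an extended international 10-20 layout with the two
mastoids (M1/M2) included as reference channels and CPz present as the
online-reference site.  Positions are taken from MNE's standard 10-05
template, re-centred on the spherical head model's origin and projected onto
the unit sphere; physical electrode locations are recovered as
``origin + head_radius * position``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

#: Sphere-model origin in the MNE head frame (metres): least-squares sphere
#: fit to the 62 scalp positions of the standard 10-05 template.
SPHERE_ORIGIN = np.array([0.001, -0.0163, 0.004])

#: Head (outer sphere) radius in metres, from the same fit.
HEAD_RADIUS = 0.0956

#: Mastoid reference channels, excluded from the scalp feature set.
MASTOIDS = ("M1", "M2")

# 62 scalp channels in canonical row order, plus the two mastoids.
CANONICAL_64 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "Iz",
    "M1", "M2",
]

# Channels drawn first when a reduced montage is requested.  The stimulation
# sites (FC3/CP3), the online reference (CPz) and the mastoids always survive.
_PRIORITY = [
    "FC3", "C3", "CP3", "CPz", "Cz", "Pz", "M1", "M2",
    "Fz", "Oz", "F3", "P3", "FC4", "C4", "CP4", "O2",
    "FCz", "O1", "F4", "P4", "CP5", "FC5", "C5", "CP1", "FC1", "C1",
]


@dataclass(frozen=True)
class Montage:
    """An ordered electrode set with unit-sphere positions.

    Attributes
    ----------
    names : list of str
        Channel labels, canonical row order.
    positions : ndarray, shape (n, 3)
        Unit vectors from the sphere-model origin towards each electrode.
    head_radius : float
        Outer sphere radius in metres.
    origin : ndarray, shape (3,)
        Sphere origin in the head coordinate frame (metres).
    adjacency : ndarray of bool, shape (n_scalp, n_scalp)
        Symmetric neighbour graph over the scalp channels (mastoids
        excluded), aligned with :attr:`scalp_names`.
    """

    names: list[str]
    positions: np.ndarray
    head_radius: float = HEAD_RADIUS
    origin: np.ndarray = field(default_factory=lambda: SPHERE_ORIGIN.copy())
    adjacency: np.ndarray = None  # type: ignore[assignment]

    @property
    def scalp_names(self) -> list[str]:
        return [n for n in self.names if n not in MASTOIDS]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def scalp_index(self, name: str) -> int:
        return self.scalp_names.index(name)

    def electrode_xyz(self) -> np.ndarray:
        """Absolute electrode positions in the head frame (metres)."""
        return self.origin + self.head_radius * self.positions

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tx\ty\tz\n")
            for name, p in zip(self.names, self.positions):
                fh.write(f"{name}\t{p[0]:.9f}\t{p[1]:.9f}\t{p[2]:.9f}\n")

    @classmethod
    def from_tsv(cls, path, neighbor_threshold: float = 0.4) -> "Montage":
        names, pos = [], []
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("name")
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                names.append(parts[0])
                pos.append([float(v) for v in parts[1:4]])
        return _assemble(names, np.asarray(pos), neighbor_threshold)


def _standard_positions(names: list[str]) -> np.ndarray:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    pos = np.array([ch_pos[n] for n in names]) - SPHERE_ORIGIN
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def _neighbor_graph(unit_pos: np.ndarray, threshold: float) -> np.ndarray:
    d = np.linalg.norm(unit_pos[:, None, :] - unit_pos[None, :, :], axis=-1)
    adj = d < threshold
    np.fill_diagonal(adj, False)
    return adj


def _assemble(names, unit_pos, neighbor_threshold) -> Montage:
    scalp = [i for i, n in enumerate(names) if n not in MASTOIDS]
    adj = _neighbor_graph(unit_pos[scalp], neighbor_threshold)
    return Montage(names=list(names), positions=unit_pos, adjacency=adj)


def make_montage(n_channels: int = 64,
                 neighbor_threshold: float | None = None) -> Montage:
    """Build a montage of ``n_channels`` electrodes including M1/M2 and CPz.

    ``n_channels = 64`` gives the full extended 10-20 layout (62 scalp
    channels + 2 mastoids).  Reduced montages (8 <= n < 64) keep the
    stimulation-relevant left-central channels and the references, for fast
    tests.  Channels are neighbours when their unit-sphere distance is below
    ``neighbor_threshold`` (0.4, i.e. 0.4 x head radius, at full density).
    With ``neighbor_threshold=None`` the threshold starts at 0.4 and is
    scaled up until the scalp graph is connected, since sparse test montages
    have proportionally larger inter-electrode spacing.
    """
    if not 8 <= n_channels <= 64:
        raise ConfigurationError(
            f"n_channels must be in [8, 64], got {n_channels}"
        )
    if n_channels == 64:
        chosen = list(CANONICAL_64)
    else:
        picked: list[str] = []
        for name in _PRIORITY + [n for n in CANONICAL_64 if n not in _PRIORITY]:
            if len(picked) == n_channels:
                break
            if name not in picked:
                picked.append(name)
        chosen = [n for n in CANONICAL_64 if n in picked]
    unit_pos = _standard_positions(chosen)
    if neighbor_threshold is None:
        neighbor_threshold = 0.4
        while neighbor_threshold < 2.0 and not _connected(
                unit_pos, chosen, neighbor_threshold):
            neighbor_threshold *= 1.2
    m = _assemble(chosen, unit_pos, neighbor_threshold)
    _validate(m)
    return m


def _connected(unit_pos, names, threshold) -> bool:
    from scipy.sparse import csgraph, csr_matrix

    scalp = [i for i, n in enumerate(names) if n not in MASTOIDS]
    adj = _neighbor_graph(unit_pos[scalp], threshold)
    if not adj.any(axis=1).all():
        return False
    n_comp, _ = csgraph.connected_components(csr_matrix(adj), directed=False)
    return n_comp == 1


def _validate(m: Montage) -> None:
    if len(set(m.names)) != len(m.names):
        raise ConfigurationError("duplicate channel names")
    norms = np.linalg.norm(m.positions, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ConfigurationError("positions must be unit-norm")
    if not np.array_equal(m.adjacency, m.adjacency.T):
        raise ConfigurationError("neighbour graph must be symmetric")
    if m.adjacency.any(axis=1).sum() < len(m.scalp_names):
        raise ConfigurationError("every scalp channel needs >= 1 neighbour")
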