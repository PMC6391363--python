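"""Electrode montage: labels and unit-sphere positions.

The packaged default is a 60-channel approximately equidistant scalp layout
(a 10-10 subset with the lateral P11/P12, O9/O10 and the older PO1/PO2 names)
recorded against an Fpz reference.  Positions are idealized spherical-head
coordinates; they are used for spatial spread of simulated components, for
spatially correlated noise, and for the spherical-spline CSD transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["Montage", "load_default_montage"]


@dataclass(frozen=True)
class Montage:
    """Set of named electrodes on the unit sphere.

    Parameters
    ----------
    labels : tuple of str
        EEG channel labels (the reference is not included).
    positions : ndarray, shape (n_channels, 3)
        Unit vectors; x = right, y = front, z = up.
    reference : str or None
        Label of the recording reference electrode, if known.
    """

    labels: tuple
    positions: np.ndarray
    reference: str | None = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        labels = tuple(self.labels)
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must have unit norm (1e-9)")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(labels)})

    def __len__(self):
        return len(self.labels)

    def __contains__(self, label):
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def cosines(self) -> np.ndarray:
        """Pairwise cosine of the angle between electrodes (n x n)."""
        return np.clip(self.positions @ self.positions.T, -1.0, 1.0)

    def angular_distance(self, a: str, b: str) -> float:
        """Great-circle angle in radians between two electrodes."""
        c = float(np.clip(self.positions[self.index(a)] @ self.positions[self.index(b)], -1, 1))
        return float(np.arccos(c))

    def neighbor_rank(self, a: str, b: str) -> int:
        """Rank of ``b`` among channels ordered by distance from ``a`` (0 = a itself)."""
        d = np.arccos(np.clip(self.positions @ self.positions[self.index(a)], -1, 1))
        order = np.argsort(d, kind="stable")
        return int(np.where(order == self.index(b))[0][0])

    def subset(self, labels) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx], reference=self.reference)


def load_default_montage() -> Montage:
    """Load the packaged 60-channel layout (Fpz reference excluded from channels)."""
    with resources.files("primeconflict.data").joinpath("montage60.tsv").open() as fh:
        tab = pd.read_csv(fh, sep="\t")
    ref_rows = tab[tab["role"] == "ref"]
    reference = ref_rows["label"].iloc[0] if len(ref_rows) else None
    tab = tab[tab["role"] == "eeg"]
    az = np.deg2rad(tab["azimuth_deg"].to_numpy())
    el = np.deg2rad(tab["elevation_deg"].to_numpy())
    pos = np.column_stack([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(tuple(tab["label"]), pos, reference=reference)
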