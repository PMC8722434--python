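"""Scalp montage: electrode names, regions, positions and neighbour graph.

The default montage is the 32-channel 10/20 layout used throughout the
package (Fp1 ... O2).  Electrodes are grouped into the five classical scalp
regions (frontal, central, temporal, parietal, occipital); the neighbour
graph drives the Hjorth nearest-neighbour surface Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

REGIONS = ("frontal", "central", "temporal", "parietal", "occipital")


class MontageError(ValueError):
    """Raised when data and montage disagree or an electrode is unknown."""


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout with regions and a neighbour relation.

    Parameters
    ----------
    name : str
        Identifier of the layout.
    names : tuple of str
        Electrode labels in channel order.
    positions : dict
        Electrode -> (x, y) on the unit disc, x toward the right ear and
        y toward the nasion.  Used for plotting only.
    region : dict
        Electrode -> one of :data:`REGIONS`.
    neighbors : dict
        Electrode -> frozenset of adjacent electrode labels (symmetric).
    """

    name: str
    names: tuple
    positions: dict
    region: dict
    neighbors: dict
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})
        if len(self._index) != len(self.names):
            raise MontageError("duplicate electrode labels")
        for n in self.names:
            if self.region.get(n) not in REGIONS:
                raise MontageError(f"electrode {n!r} has no valid region")
            nb = self.neighbors.get(n, frozenset())
            if len(nb) < 2:
                raise MontageError(f"electrode {n!r} has fewer than 2 neighbours")
            for m in nb:
                if n not in self.neighbors[m]:
                    raise MontageError(f"asymmetric adjacency {n!r}-{m!r}")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise MontageError(f"unknown electrode {name!r}") from None

    def region_of(self, name: str) -> str:
        self.index(name)
        return self.region[name]

    def channels_in_region(self, region: str) -> list:
        if region not in REGIONS:
            raise MontageError(f"unknown region {region!r}")
        return [n for n in self.names if self.region[n] == region]

    def neighbor_indices(self) -> list:
        """Per-channel neighbour index lists, in channel order."""
        return [sorted(self._index[m] for m in self.neighbors[n]) for n in self.names]

    def position_array(self) -> np.ndarray:
        return np.array([self.positions[n] for n in self.names], dtype=float)


def montage_from_dict(spec: dict) -> Montage:
    names = tuple(spec["names"])
    region = {}
    for reg, members in spec["regions"].items():
        for n in members:
            region[n] = reg
    neighbors = {n: set() for n in names}
    for a, b in spec["adjacency"]:
        neighbors[a].add(b)
        neighbors[b].add(a)
    positions = {n: tuple(map(float, spec["positions"][n])) for n in names}
    return Montage(
        name=spec.get("name", "custom"),
        names=names,
        positions=positions,
        region=region,
        neighbors={n: frozenset(v) for n, v in neighbors.items()},
    )


def load_montage(path=None) -> Montage:
    """Load a montage from a YAML file; default is the shipped 10/20 layout."""
    if path is None:
        ref = resources.files("eegfp.data") / "montage_1020_32.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return montage_from_dict(yaml.safe_load(text))


_DEFAULT = None


def default_montage() -> Montage:
    """The shipped 32-channel 10/20 montage (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_montage()
    return _DEFAULT
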