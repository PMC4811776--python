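"""Region labels, coordinates and the default prefrontal connection graph.

The six left-lateral-prefrontal regions are ordered rostral to caudal by
their MNI y-coordinate.  Level assignment groups the two caudal regions
(SFS, IFJ) and the two mid regions (cMFG, IFS); MFG and FPl each occupy
their own rostral level.  Edges joining regions at the same level are the
dorsal/ventral connections that hierarchy metrics ignore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGIONS: tuple[str, ...] = ("FPl", "MFG", "IFS", "cMFG", "IFJ", "SFS")

#: MNI peak coordinates (mm).  Caudal regions (IFJ, SFS) use the
#: stimulus-domain-contrast peaks used for all connectivity analyses.
MNI_COORDS: dict[str, tuple[float, float, float]] = {
    "FPl": (-44.0, 48.0, 4.0),
    "MFG": (-38.0, 28.0, 44.0),
    "IFS": (-52.0, 20.0, 28.0),
    "cMFG": (-34.0, 10.0, 60.0),
    "IFJ": (-38.0, 6.0, 26.0),
    "SFS": (-22.0, 0.0, 54.0),
}

#: Rostral/caudal level: higher = more rostral.
LEVELS: dict[str, int] = {"FPl": 3, "MFG": 2, "IFS": 1, "cMFG": 1, "IFJ": 0, "SFS": 0}

#: Coarse zone used by behavior analyses (pooling dorsal/ventral pairs).
ZONES: dict[str, str] = {
    "FPl": "rostral",
    "MFG": "rostral",
    "IFS": "mid",
    "cMFG": "mid",
    "IFJ": "caudal",
    "SFS": "caudal",
}

#: Default fixed-connectivity graph: nine bidirectional pairs.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("FPl", "MFG"),
    ("FPl", "IFS"),
    ("FPl", "cMFG"),
    ("MFG", "IFS"),
    ("MFG", "cMFG"),
    ("cMFG", "SFS"),
    ("IFS", "IFJ"),
    ("SFS", "IFJ"),
    ("cMFG", "IFS"),
)


@dataclass(frozen=True)
class RegionGeometry:
    """Region labels with MNI coordinates and rostral/caudal levels."""

    labels: tuple[str, ...] = REGIONS
    coords: dict[str, tuple[float, float, float]] = field(default_factory=lambda: dict(MNI_COORDS))
    levels: dict[str, int] = field(default_factory=lambda: dict(LEVELS))

    def __post_init__(self) -> None:
        missing = [r for r in self.labels if r not in self.coords or r not in self.levels]
        if missing:
            raise ValueError(f"geometry missing coordinates/levels for {missing}")

    def y(self, label: str) -> float:
        """Rostral/caudal (MNI y) position of a region, mm."""
        return self.coords[label][1]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def same_level(self, a: str, b: str) -> bool:
        """True for dorsal/ventral pairs sitting at one rostral/caudal level."""
        return self.levels[a] == self.levels[b]

    def rostral_caudal_edges(
        self, edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES
    ) -> tuple[tuple[str, str], ...]:
        """Edges that span rostral/caudal levels (dorsal/ventral pairs removed)."""
        return tuple((a, b) for a, b in edges if not self.same_level(a, b))


DEFAULT_GEOMETRY = RegionGeometry()
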