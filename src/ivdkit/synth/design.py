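"""Study design and reproducible random substreams.

The cohort layout mirrors a three-group ovine annular-lesion trial: lesion
animals belong to an early-acute (EA), late-acute (LA) or established/chronic
(EST) group and receive either a vehicle (PBS) or a mesenchymal stromal cell
(MSC) intradiscal injection; nonoperated controls (NOC) receive nothing.
Each animal contributes three lumbar disc levels with a fixed division of
labour — L1L2 histology, L3L4 gene expression, L5L6 biomechanics — and each
disc is zonally dissected into outer/inner annulus (AF1, AF2) and nucleus
pulposus (NP) for the biochemical and expression assays.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

GROUPS = ("EA", "LA", "EST", "NOC")
ARMS = ("PBS", "MSC", "none")
DISC_LEVELS = ("L1L2", "L3L4", "L5L6")
ZONES = ("AF1", "AF2", "NP")
LOADING_MODES = ("flexion_extension", "lateral_bending", "axial_rotation")

#: disc level dedicated to each analysis stage
LEVEL_FOR = {"histology": "L1L2", "expression": "L3L4", "biomechanics": "L5L6"}


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a named, reproducible child generator of the study seed.

    All randomness in the synthetic study flows from one integer seed; each
    table/stage draws from its own substream so that regenerating one stage
    never perturbs another.  Names are hashed (CRC-32) into the spawn key.
    """
    key = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: which (group, arm) cells exist and how big they are."""

    groups: tuple[str, ...] = ("EA", "LA", "EST", "NOC")
    n_sheep_per_cell: int = 6
    disc_levels: tuple[str, ...] = DISC_LEVELS
    zones: tuple[str, ...] = ZONES
    seed: int = 0
    arms_lesion: tuple[str, ...] = field(default=("PBS", "MSC"))

    def __post_init__(self) -> None:
        if self.n_sheep_per_cell < 1:
            raise ValueError("n_sheep_per_cell must be >= 1")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if set(self.arms_lesion) - {"PBS", "MSC"}:
            raise ValueError("lesion arms must be a subset of {PBS, MSC}")

    def cells(self) -> list[tuple[str, str]]:
        """(group, arm) cells; NOC pairs only with arm='none'."""
        out: list[tuple[str, str]] = []
        for g in self.groups:
            if g == "NOC":
                out.append((g, "none"))
            else:
                out.extend((g, a) for a in self.arms_lesion)
        return out

    def sheep_ids(self) -> list[tuple[str, str, str]]:
        """(sheep_id, group, arm) for every animal in the study."""
        out = []
        for g, a in self.cells():
            for i in range(1, self.n_sheep_per_cell + 1):
                out.append((f"{g}-{a}-{i:02d}", g, a))
        return out

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        """Load a design from a YAML config (keys mirror the field names)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        listy = {k: tuple(v) for k, v in raw.items() if isinstance(v, list)}
        return cls(**{**raw, **listy})

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
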