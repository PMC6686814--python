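"""Disc height index (DHI) radiogrammetry from landmark coordinates.

Disc height is the mean of three measurement lines (anterior, middle,
posterior) across the disc space; each line's length is the projection of
the landmark-pair difference onto the local spine axis, defined by the line
joining the two vertebral-body centroids.  The DHI normalises disc height to
the mean of the two adjacent vertebral body heights,

    DHI = 2 * disc_height / (vb_height_cranial + vb_height_caudal),

which cancels radiographic magnification and rotation, and %DHI expresses an
endpoint DHI as a percentage of the pre-surgery DHI of the same disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_POSITIONS = ("ant", "mid", "post")
POINT_NAMES = tuple(
    f"{body}_{pos}_{edge}"
    for body in ("cranial", "caudal")
    for pos in _POSITIONS
    for edge in ("superior", "inferior")
)


@dataclass(frozen=True)
class RadiographLandmarks:
    """Named 2-D landmarks for one disc level at one timepoint."""

    disc_level: str
    timepoint: str
    points: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = [n for n in POINT_NAMES if n not in self.points]
        if missing:
            raise ValueError(f"missing landmark point(s): {missing}")
        for name, (x, y) in self.points.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinate for point {name}")

    def _p(self, name: str) -> np.ndarray:
        return np.asarray(self.points[name], dtype=float)


@dataclass(frozen=True)
class DhiResult:
    disc_level: str
    disc_height: float
    vb_height_cranial: float
    vb_height_caudal: float
    dhi: float
    percent_dhi: float | None = None


def _spine_axis(lm: RadiographLandmarks) -> np.ndarray:
    """Unit vector from caudal to cranial vertebral-body centroid."""
    cran = np.mean(
        [lm._p(f"cranial_{p}_{e}") for p in _POSITIONS for e in ("superior", "inferior")], axis=0
    )
    caud = np.mean(
        [lm._p(f"caudal_{p}_{e}") for p in _POSITIONS for e in ("superior", "inferior")], axis=0
    )
    v = cran - caud
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate landmarks: coincident vertebral body centroids")
    return v / n


def _axial_span(lm: RadiographLandmarks, top: str, bottom: str, axis: np.ndarray) -> float:
    return float(abs(np.dot(lm._p(top) - lm._p(bottom), axis)))


def disc_height(lm: RadiographLandmarks) -> float:
    """Mean of the anterior/middle/posterior disc-space distances."""
    axis = _spine_axis(lm)
    spans = [
        _axial_span(lm, f"cranial_{p}_inferior", f"caudal_{p}_superior", axis) for p in _POSITIONS
    ]
    return float(np.mean(spans))


def vb_heights(lm: RadiographLandmarks) -> tuple[float, float]:
    """(cranial, caudal) vertebral body heights along the spine axis."""
    axis = _spine_axis(lm)
    cran = np.mean(
        [_axial_span(lm, f"cranial_{p}_superior", f"cranial_{p}_inferior", axis) for p in _POSITIONS]
    )
    caud = np.mean(
        [_axial_span(lm, f"caudal_{p}_superior", f"caudal_{p}_inferior", axis) for p in _POSITIONS]
    )
    return float(cran), float(caud)


def dhi(lm: RadiographLandmarks) -> DhiResult:
    """Disc height index of one landmark set."""
    dh = disc_height(lm)
    h_cran, h_caud = vb_heights(lm)
    if h_cran <= 0 or h_caud <= 0:
        raise ValueError("zero vertebral body height")
    return DhiResult(
        disc_level=lm.disc_level,
        disc_height=dh,
        vb_height_cranial=h_cran,
        vb_height_caudal=h_caud,
        dhi=2 * dh / (h_cran + h_caud),
    )


def percent_dhi(endpoint: RadiographLandmarks, pre: RadiographLandmarks) -> DhiResult:
    """Endpoint DHI as a percentage of the pre-surgery DHI."""
    if endpoint.disc_level != pre.disc_level:
        raise ValueError("timepoints belong to different disc levels")
    r_end = dhi(endpoint)
    r_pre = dhi(pre)
    return DhiResult(
        disc_level=r_end.disc_level,
        disc_height=r_end.disc_height,
        vb_height_cranial=r_end.vb_height_cranial,
        vb_height_caudal=r_end.vb_height_caudal,
        dhi=r_end.dhi,
        percent_dhi=100.0 * r_end.dhi / r_pre.dhi,
    )
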