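"""Synthetic radiographic landmark tables for disc height measurement.

Each disc level at each timepoint yields a set of 12 named 2-D landmarks:
anterior/middle/posterior points on the caudal edge of the cranial vertebral
body, the cranial edge of the caudal vertebral body, and the outer corners
of both bodies.  Endpoint disc spaces are scaled by a per-disc draw of the
disc-height ratio; vertebral body heights are unchanged.  Every landmark set
is passed through a random similarity transform (magnification, rotation,
translation) emulating uncontrolled radiographic geometry, which the disc
height index must cancel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..radiograph import POINT_NAMES, RadiographLandmarks
from .design import StudyDesign, substream

# base geometry (image units): vertebral body 20 tall x 30 deep, disc space 4
VB_HEIGHT = 20.0
VB_DEPTH = 30.0
DISC_HEIGHT = 4.0


def _base_points(disc_height: float) -> dict[str, tuple[float, float]]:
    half = disc_height / 2.0
    xs = {"ant": -VB_DEPTH / 2, "mid": 0.0, "post": VB_DEPTH / 2}
    pts: dict[str, tuple[float, float]] = {}
    for pos, x in xs.items():
        pts[f"cranial_{pos}_inferior"] = (x, half)
        pts[f"cranial_{pos}_superior"] = (x, half + VB_HEIGHT)
        pts[f"caudal_{pos}_superior"] = (x, -half)
        pts[f"caudal_{pos}_inferior"] = (x, -half - VB_HEIGHT)
    return pts


def _similarity(pts: dict, rng: np.random.Generator, jitter: bool) -> dict:
    if not jitter:
        return dict(pts)
    s = rng.uniform(0.85, 1.25)
    phi = np.deg2rad(rng.uniform(-8.0, 8.0))
    c, sn = np.cos(phi), np.sin(phi)
    tx, ty = rng.uniform(-20, 20, size=2)
    return {
        k: (s * (c * x - sn * y) + tx, s * (sn * x + c * y) + ty) for k, (x, y) in pts.items()
    }


def transform_landmarks(
    lm: RadiographLandmarks, scale: float, angle_deg: float, tx: float, ty: float
) -> RadiographLandmarks:
    """Apply an explicit similarity transform to a landmark set."""
    phi = np.deg2rad(angle_deg)
    c, s = np.cos(phi), np.sin(phi)
    pts = {
        k: (scale * (c * x - s * y) + tx, scale * (s * x + c * y) + ty)
        for k, (x, y) in lm.points.items()
    }
    return RadiographLandmarks(lm.disc_level, lm.timepoint, pts)


def landmark_set(
    disc_level: str,
    timepoint: str,
    disc_height: float,
    rng: np.random.Generator | None = None,
    jitter: bool = True,
) -> RadiographLandmarks:
    """One synthetic landmark set with a known true disc height."""
    rng = rng or np.random.default_rng(0)
    return RadiographLandmarks(
        disc_level=disc_level,
        timepoint=timepoint,
        points=_similarity(_base_points(disc_height), rng, jitter),
    )


def generate_landmarks(
    preset, design: StudyDesign, seed: int, jitter: bool = True, label: str | None = None
) -> pd.DataFrame:
    """Paired pre-surgery / endpoint landmark tables for one cohort preset.

    Returns a long table (sheep, disc_level, timepoint, point, x, y) plus a
    ``true_dhi_ratio`` column carrying the generator ground truth.  ``label``
    names the cohort (default: the preset name) and seeds its substream.
    """
    label = label or preset.name
    rng = substream(seed, "landmarks", label)
    rows = []
    for i in range(1, design.n_sheep_per_cell + 1):
        sheep = f"{label}-{i:02d}"
        for level in design.disc_levels:
            ratio = -1.0
            while ratio <= 0:
                ratio = rng.normal(preset.dhi_ratio_mean, preset.dhi_ratio_sd)
            for tp, dh in (("pre_surgery", DISC_HEIGHT), ("endpoint", DISC_HEIGHT * ratio)):
                lm = landmark_set(level, tp, dh, rng, jitter=jitter)
                for name in POINT_NAMES:
                    x, y = lm.points[name]
                    rows.append(
                        {
                            "sheep": sheep,
                            "disc_level": level,
                            "timepoint": tp,
                            "point": name,
                            "x": x,
                            "y": y,
                            "true_dhi_ratio": ratio,
                        }
                    )
    return pd.DataFrame(rows)


def landmarks_from_frame(df: pd.DataFrame) -> RadiographLandmarks:
    """Rebuild one landmark set from rows of a long landmark table."""
    pts = {r.point: (float(r.x), float(r.y)) for r in df.itertuples()}
    return RadiographLandmarks(
        disc_level=str(df["disc_level"].iloc[0]),
        timepoint=str(df["timepoint"].iloc[0]),
        points=pts,
    )
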