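"""Cumulative histopathology scoring of disc sections.

Six ordinal criteria are scored per disc section: (a) toluidine-blue GAG
staining, (b) structural characteristics of the lesion, (c) cellular
morphology, (d) blood-vessel ingrowth, (e) cellular infiltration and
(f) special degenerative/repair features (chondroid metaplasia, cystic
degeneration, matrix denudation).  The cumulative score is their sum.  Two
blinded observers score each section independently; the consensus profile
is the per-criterion mean rounded half-up to the ordinal grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CRITERIA = (
    "a_gag_staining",
    "b_structure",
    "c_cell_morphology",
    "d_vessel_ingrowth",
    "e_cell_infiltration",
    "f_special_features",
)


@dataclass(frozen=True)
class ScoringScheme:
    """Ordinal range [0, max] per criterion; ranges are configurable."""

    criterion_max: dict[str, int] = field(
        default_factory=lambda: {c: 5 for c in CRITERIA}
    )

    def __post_init__(self) -> None:
        if len(set(self.criterion_max)) != len(self.criterion_max):
            raise ValueError("duplicate criterion ids")  # pragma: no cover
        for c, m in self.criterion_max.items():
            if int(m) < 1:
                raise ValueError(f"criterion {c}: max must be >= 1")

    @property
    def criteria(self) -> tuple[str, ...]:
        return tuple(self.criterion_max)

    @property
    def scheme_max(self) -> int:
        return sum(self.criterion_max.values())


@dataclass(frozen=True)
class HistoProfile:
    """Per-criterion scores for one disc section by one observer."""

    disc_id: str
    observer: str
    scores: dict[str, int]


def cumulative_score(profile: HistoProfile, scheme: ScoringScheme) -> int:
    """Sum of the criterion scores, validated against the scheme."""
    total = 0
    for c, m in scheme.criterion_max.items():
        if c not in profile.scores:
            raise ValueError(f"missing criterion {c}")
        s = profile.scores[c]
        if not (0 <= s <= m) or int(s) != s:
            raise ValueError(f"criterion {c}: score {s} outside [0, {m}]")
        total += int(s)
    extra = set(profile.scores) - set(scheme.criterion_max)
    if extra:
        raise ValueError(f"unknown criteria: {sorted(extra)}")
    return total


def reconcile_observers(profiles: list[HistoProfile]) -> tuple[HistoProfile, dict[str, int]]:
    """Consensus profile (per-criterion mean, rounded half-up) and the
    maximum absolute inter-observer disagreement per criterion."""
    if not profiles:
        raise ValueError("no observer profiles")
    disc_ids = {p.disc_id for p in profiles}
    if len(disc_ids) != 1:
        raise ValueError(f"conflicting disc ids: {sorted(disc_ids)}")
    criteria = profiles[0].scores.keys()
    consensus: dict[str, int] = {}
    disagreement: dict[str, int] = {}
    for c in criteria:
        vals = [p.scores[c] for p in profiles]
        consensus[c] = int(math.floor(np.mean(vals) + 0.5))  # round half-up
        disagreement[c] = int(max(vals) - min(vals))
    return (
        HistoProfile(disc_id=profiles[0].disc_id, observer="consensus", scores=consensus),
        disagreement,
    )


def cohort_scores(scores: "pd.Series | np.ndarray | list[float]") -> dict[str, float]:
    """Five-number box-plot summary plus mean/SD of cumulative scores."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 discs for a cohort summary")
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "median": float(np.median(x)),
        "q25": float(np.quantile(x, 0.25)),
        "q75": float(np.quantile(x, 0.75)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def consensus_cumulative_scores(
    profiles: pd.DataFrame, scheme: ScoringScheme
) -> pd.DataFrame:
    """Per-disc consensus cumulative scores from a long score-sheet table.

    Expects columns (disc_id, observer, criterion, score); extra grouping
    columns (sheep, group, arm, ...) are carried through.
    """
    carry = [
        c for c in profiles.columns if c not in ("disc_id", "observer", "criterion", "score")
    ]
    rows = []
    for disc_id, g in profiles.groupby("disc_id", sort=False):
        obs_profiles = [
            HistoProfile(
                disc_id=str(disc_id),
                observer=str(obs),
                scores={r.criterion: int(r.score) for r in og.itertuples()},
            )
            for obs, og in g.groupby("observer", sort=False)
        ]
        consensus, _ = reconcile_observers(obs_profiles)
        row = {"disc_id": disc_id, "cumulative": cumulative_score(consensus, scheme)}
        for c in carry:
            row[c] = g[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
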