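"""Modified Gensini score for angiographic severity of coronary atherosclerosis.

Each coronary-segment lesion earns stenosis points that double per band of
luminal narrowing (1 for 0-25% up to 32 for total occlusion), weighted by a
multiplier reflecting the physiological importance of the territory the
segment supplies (5 for the left main down to 0.5 for small branches).
The per-segment weighted points are summed over a patient's lesions.
Acute total occlusion is treated as a non-critical lesion: it takes the
lowest-band point value and its weighted contribution is capped at 5,
because acute occlusions typically arise from previously non-critical
plaque rather than from long-standing high-grade stenosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SEGMENT_MULTIPLIERS",
    "SEGMENTS",
    "LesionRecord",
    "GensiniResult",
    "stenosis_points",
    "segment_multiplier",
    "modified_gensini",
    "score_lesion_table",
    "dichotomize_severity",
]

#: Segment vocabulary with importance multipliers.  Left main = 5; proximal
#: LAD and proximal circumflex = 2.5; mid LAD = 1.5; second diagonal and
#: posterolateral = 0.5; every other listed segment = 1.
SEGMENT_MULTIPLIERS: dict[str, float] = {
    "left_main": 5.0,
    "proximal_LAD": 2.5,
    "proximal_LCX": 2.5,
    "mid_LAD": 1.5,
    "second_diagonal": 0.5,
    "posterolateral": 0.5,
    "distal_LAD": 1.0,
    "first_diagonal": 1.0,
    "distal_LCX": 1.0,
    "obtuse_marginal": 1.0,
    "proximal_RCA": 1.0,
    "mid_RCA": 1.0,
    "distal_RCA": 1.0,
    "posterior_descending": 1.0,
}

#: Aliases accepted on input (case-insensitive match after normalization).
_ALIASES = {
    "mlca": "left_main",
    "lm": "left_main",
    "plad": "proximal_LAD",
    "plcx": "proximal_LCX",
    "mlad": "mid_LAD",
}

SEGMENTS = tuple(SEGMENT_MULTIPLIERS)

_OCCLUSION_CAP = 5.0  # non-critical contribution ceiling for acute occlusion


@dataclass(frozen=True)
class LesionRecord:
    """One coronary segment's stenosis observation for one subject."""

    subject_id: str
    segment: str
    stenosis_pct: float
    acute_occlusion: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "segment", normalize_segment(self.segment))
        if not (0.0 <= self.stenosis_pct <= 100.0):
            raise ValueError(f"stenosis_pct must lie in [0, 100], got {self.stenosis_pct}")


@dataclass(frozen=True)
class GensiniResult:
    subject_id: str
    score: float
    per_segment_contributions: tuple[tuple[str, int, float, float], ...]
    """Tuples of (segment, points, multiplier, weighted contribution)."""


def normalize_segment(segment: str) -> str:
    key = str(segment).strip()
    low = key.lower()
    if low in _ALIASES:
        return _ALIASES[low]
    for name in SEGMENT_MULTIPLIERS:
        if low == name.lower():
            return name
    raise KeyError(
        f"unknown coronary segment {segment!r}; accepted labels: {sorted(SEGMENT_MULTIPLIERS)}"
    )


def stenosis_points(stenosis_pct: float) -> int:
    """Map percent luminal narrowing onto the doubling point scale.

    Bands are half-open on the real line so that any continuous estimate
    maps unambiguously and the printed integer bands are respected:
    [0,25] -> 1, (25,50] -> 2, (50,75] -> 4, (75,90] -> 8, (90,100) -> 16,
    exactly 100 -> 32.
    """
    s = float(stenosis_pct)
    if not (0.0 <= s <= 100.0):
        raise ValueError(f"stenosis percent must lie in [0, 100], got {s}")
    if s == 100.0:
        return 32
    if s > 90.0:
        return 16
    if s > 75.0:
        return 8
    if s > 50.0:
        return 4
    if s > 25.0:
        return 2
    return 1


def segment_multiplier(segment: str) -> float:
    """Importance multiplier for a (normalized or alias) segment label."""
    return SEGMENT_MULTIPLIERS[normalize_segment(segment)]


def modified_gensini(lesions) -> GensiniResult:
    """Score one subject's lesion set.

    ``lesions`` is an iterable of :class:`LesionRecord` (or a DataFrame with
    the lesion columns), all sharing one subject id.  An empty lesion set
    scores 0.  Acute total occlusions contribute
    ``min(1 x multiplier, 5)`` — the non-critical band value, capped.
    """
    if isinstance(lesions, pd.DataFrame):
        lesions = [
            LesionRecord(str(r.subject_id), str(r.segment), float(r.stenosis_pct),
                         bool(r.acute_occlusion))
            for r in lesions.itertuples(index=False)
        ]
    else:
        lesions = list(lesions)
    if not lesions:
        return GensiniResult(subject_id="", score=0.0, per_segment_contributions=())
    ids = {l.subject_id for l in lesions}
    if len(ids) != 1:
        raise ValueError(f"lesions span multiple subjects: {sorted(ids)}")
    contributions = []
    for l in lesions:
        mult = segment_multiplier(l.segment)
        if l.acute_occlusion:
            points = 1
            weighted = min(points * mult, _OCCLUSION_CAP)
        else:
            points = stenosis_points(l.stenosis_pct)
            weighted = points * mult
        contributions.append((l.segment, points, mult, weighted))
    score = float(sum(c[3] for c in contributions))
    return GensiniResult(subject_id=lesions[0].subject_id, score=score,
                         per_segment_contributions=tuple(contributions))


def score_lesion_table(lesions: pd.DataFrame) -> pd.DataFrame:
    """Score every subject in a lesion table.

    Expects columns subject_id, segment, stenosis_pct, acute_occlusion;
    returns a DataFrame (subject_id, score) with one row per subject.
    """
    required = {"subject_id", "segment", "stenosis_pct", "acute_occlusion"}
    missing = required - set(lesions.columns)
    if missing:
        raise KeyError(f"lesion table missing columns: {sorted(missing)}")
    rows = [
        {"subject_id": sid, "score": modified_gensini(group).score}
        for sid, group in lesions.groupby("subject_id", sort=True)
    ]
    return pd.DataFrame(rows, columns=["subject_id", "score"])


def dichotomize_severity(scores, cutoff="median") -> tuple[np.ndarray, float]:
    """Split severity scores into low/high at a cutoff (strictly greater = high).

    ``cutoff="median"`` uses the sample median and reports it; returns the
    binary vector (1 = high severity) and the cutoff actually used.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot dichotomize an empty score vector")
    cut = float(np.median(arr)) if cutoff == "median" else float(cutoff)
    return (arr > cut).astype(int), cut
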