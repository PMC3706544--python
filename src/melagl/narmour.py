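"""Quantified Narmour implication-realization factors.

In a window of three consecutive tones, the first interval is *implicative*
(I) and the second *realised* (R).  Six bottom-up factors score how strongly
the realised interval conforms to the expectancy set up by the implicative
one: revised registral direction (rd), registral return (rr), intervallic
difference (id), graded proximity (pr), closure (cl), and consonance (co).
All factors are coded as predictability scores: higher means more consistent
with common melodic practice.

The verbal principles leave numeric codings open; the tables used here are
fixed in :class:`ScoringConfig` and the scalar rules below, are switchable by
configuration, and only their relative scale matters downstream (mapping
candidates are compared by z-scores across the candidate population).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .grammar import PitchSequence

__all__ = [
    "IntervalPair",
    "FactorVector",
    "NarmourProfile",
    "ScoringConfig",
    "FACTORS",
    "factor_scores",
    "melody_profile",
    "set_profile",
]

FACTORS = ("rd", "rr", "id", "pr", "cl", "co")

#: Consonance weights for interval sizes 0..12 semitones (unison..octave),
#: modeled on empirically derived consonance ratings of the chromatic
#: intervals, rescaled to [0, 1].  These values are configuration: any
#: monotone-equivalent vector serves, since only relative scale matters.
DEFAULT_CONSONANCE = (
    1.00,  # 0  unison
    0.12,  # 1  minor second
    0.29,  # 2  major second
    0.57,  # 3  minor third
    0.62,  # 4  major third
    0.72,  # 5  perfect fourth
    0.45,  # 6  tritone
    0.83,  # 7  perfect fifth
    0.51,  # 8  minor sixth
    0.60,  # 9  major sixth
    0.37,  # 10 minor seventh
    0.18,  # 11 major seventh
    1.00,  # 12 octave
)


@dataclass(frozen=True)
class ScoringConfig:
    """Numeric coding parameters for the six factors.

    ``small_max``/``large_min`` set the small/large interval boundary in
    semitones (the proximity threshold of 5 semitones fixes the default; the
    tritone is classed large).  ``consonance_weights`` holds 13 values for
    interval sizes 0-12; realised intervals beyond an octave are folded down
    by an octave (``octave_fold``).
    """

    small_max: int = 5
    large_min: int = 6
    consonance_weights: tuple[float, ...] = DEFAULT_CONSONANCE
    octave_fold: bool = True

    def __post_init__(self) -> None:
        if not (self.small_max < self.large_min):
            raise ValueError("small_max must be < large_min")
        if len(self.consonance_weights) != 13:
            raise ValueError("consonance_weights must have 13 entries (0-12)")

    @classmethod
    def from_yaml(cls, doc: str | Path) -> "ScoringConfig":
        text = Path(doc).read_text() if isinstance(doc, Path) else doc
        if isinstance(doc, str) and "\n" not in doc and Path(doc).exists():
            text = Path(doc).read_text()
        data = yaml.safe_load(text) or {}
        kwargs = {}
        for key in ("small_max", "large_min", "octave_fold"):
            if key in data:
                kwargs[key] = data[key]
        if "consonance_weights" in data:
            kwargs["consonance_weights"] = tuple(float(w) for w in data["consonance_weights"])
        return cls(**kwargs)


@dataclass(frozen=True)
class IntervalPair:
    """Implicative/realised interval pair from three consecutive tones."""

    implicative: int
    realised: int
    anchor: int = 0

    @classmethod
    def from_tones(cls, t1: int, t2: int, t3: int) -> "IntervalPair":
        return cls(implicative=t2 - t1, realised=t3 - t2, anchor=t1)


@dataclass(frozen=True)
class FactorVector:
    rd: float
    rr: float
    id: float
    pr: float
    cl: float
    co: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rd, self.rr, self.id, self.pr, self.cl, self.co])


@dataclass(frozen=True)
class NarmourProfile:
    """Mean factor scores over the interval pairs of a melody (or set)."""

    rd: float
    rr: float
    id: float
    pr: float
    cl: float
    co: float
    n_pairs: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.rd, self.rr, self.id, self.pr, self.cl, self.co])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FACTORS, self.as_array().tolist()))


def factor_arrays(
    I: np.ndarray, R: np.ndarray, cfg: ScoringConfig
) -> dict[str, np.ndarray]:
    """Vectorized factor coding over arrays of implicative/realised intervals.

    The scalar rules, applied elementwise:

    * rd — small implicative intervals expect continuation in the same
      direction, large ones a reversal; a lateral realisation (R = 0) counts
      as "not the same direction", so it scores after a large I only.
    * rr — realised interval reverses direction and lands within 2 semitones
      of the first tone of the window, i.e. ``|I + R| <= 2`` with R != 0.
    * id — small I expects a similar-sized R (within 3 semitones if direction
      is kept, 2 if changed); large I expects R at least 3 semitones smaller.
    * pr — graded proximity ``max(0, 6 - |R|)``.
    * cl — additive closure: +1 for a direction change, +1 for a large I
      followed by a sufficiently smaller R (shrink >= 3 same direction,
      >= 2 different direction).
    * co — consonance weight of ``|R|``, intervals beyond an octave folded.
    """
    I = np.asarray(I, dtype=np.int64)
    R = np.asarray(R, dtype=np.int64)
    absI, absR = np.abs(I), np.abs(R)
    small = absI <= cfg.small_max
    large = ~small
    sI, sR = np.sign(I), np.sign(R)
    same_dir = (sI == sR) & (sI != 0)
    diff_dir = (sR != sI)

    rd = ((small & same_dir) | (large & diff_dir)).astype(float)

    rr = (diff_dir & (sR != 0) & (np.abs(I + R) <= 2)).astype(float)

    id_small = small & (
        (same_dir & (np.abs(absR - absI) <= 3))
        | (~same_dir & (np.abs(absR - absI) <= 2))
    )
    id_large = large & (absR <= absI - 3)
    idf = (id_small | id_large).astype(float)

    pr = np.maximum(0, 6 - absR).astype(float)

    shrink_ok = large & np.where(same_dir, absR <= absI - 3, absR <= absI - 2)
    cl = diff_dir.astype(float) + shrink_ok.astype(float)

    weights = np.asarray(cfg.consonance_weights)
    folded = np.where(
        (absR > 12) & cfg.octave_fold, absR - 12 * ((absR - 1) // 12), absR
    )
    folded = np.clip(folded, 0, 12)
    co = weights[folded]

    return {"rd": rd, "rr": rr, "id": idf, "pr": pr, "cl": cl, "co": co}


def factor_scores(p: IntervalPair, cfg: ScoringConfig | None = None) -> FactorVector:
    """Score one implicative/realised interval pair (pure function)."""
    cfg = cfg or ScoringConfig()
    arrs = factor_arrays(np.array([p.implicative]), np.array([p.realised]), cfg)
    return FactorVector(**{k: float(v[0]) for k, v in arrs.items()})


def _pitches(m: PitchSequence | Sequence[int]) -> np.ndarray:
    if isinstance(m, PitchSequence):
        return np.asarray(m.pitches, dtype=np.int64)
    return np.asarray(m, dtype=np.int64)


def melody_profile(
    m: PitchSequence | Sequence[int], cfg: ScoringConfig | None = None
) -> NarmourProfile:
    """Mean factor scores over the ``n_tones - 2`` triples of a melody."""
    cfg = cfg or ScoringConfig()
    tones = _pitches(m)
    if len(tones) < 3:
        raise ValueError("melody must have at least 3 tones")
    ivals = np.diff(tones)
    arrs = factor_arrays(ivals[:-1], ivals[1:], cfg)
    means = {k: float(np.mean(v)) for k, v in arrs.items()}
    return NarmourProfile(**means, n_pairs=len(tones) - 2)


def set_profile(
    ms: Iterable[PitchSequence | Sequence[int]], cfg: ScoringConfig | None = None
) -> NarmourProfile:
    """Unweighted mean of per-melody profiles over a melody set."""
    cfg = cfg or ScoringConfig()
    profiles = [melody_profile(m, cfg) for m in ms]
    if not profiles:
        raise ValueError("empty melody set")
    mat = np.array([p.as_array() for p in profiles])
    means = mat.mean(axis=0)
    return NarmourProfile(
        **dict(zip(FACTORS, means.tolist())),
        n_pairs=int(sum(p.n_pairs for p in profiles)),
    )
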