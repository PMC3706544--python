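"""One-to-one pitch mapping search ranked by Narmour z-scores.

The stimulus manipulation keeps the grammar and its terminal structure fixed
and re-voices the surface: an injective mapping from the source pitch set
onto new pitches yields a melody set with identical abstract n-gram
structure but different melodic surface.  Candidate mappings are ranked by
the unweighted sum of the z-scores of their six mean Narmour factors, each
z-score taken across the whole candidate population, so that the selected
mapping is maximally consistent or maximally inconsistent with common
melodic expectancy.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from itertools import islice, permutations
from typing import Iterable, Sequence

import numpy as np

from .grammar import PitchSequence, TonePairAlphabet
from .narmour import FACTORS, NarmourProfile, ScoringConfig, factor_arrays

__all__ = [
    "Mapping",
    "MappingScore",
    "default_target_pool",
    "candidate_mappings",
    "apply_mapping",
    "score_mappings",
    "select_mapping",
    "ranked_report",
]

DEFAULT_MAX_SPAN = 15  # semitones: an octave widened to about a tenth


@dataclass(frozen=True)
class Mapping:
    """Injective assignment from source pitches to target pitches."""

    source_pitches: tuple[int, ...]
    target_pitches: tuple[int, ...]
    target_pool: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.source_pitches) != len(self.target_pitches):
            raise ValueError("source and target pitch lists differ in length")
        if len(set(self.target_pitches)) != len(self.target_pitches):
            raise ValueError("mapping must be injective")
        if self.target_pool and not set(self.target_pitches) <= set(self.target_pool):
            raise ValueError("mapping image must lie in the target pool")

    @property
    def assignment(self) -> dict[int, int]:
        return dict(zip(self.source_pitches, self.target_pitches))

    @property
    def span(self) -> int:
        return max(self.target_pitches) - min(self.target_pitches)

    def __str__(self) -> str:
        return " ".join(
            f"{s}:{t}" for s, t in zip(self.source_pitches, self.target_pitches)
        )

    @classmethod
    def identity(cls, source: Sequence[int]) -> "Mapping":
        src = tuple(source)
        return cls(src, src, src)


@dataclass(frozen=True)
class MappingScore:
    """Raw factor means, population z-scores, and their unweighted sum."""

    mapping: Mapping
    raw: NarmourProfile
    z: tuple[float, ...]
    total: float


def default_target_pool(
    source: TonePairAlphabet | Sequence[int], max_span: int = DEFAULT_MAX_SPAN
) -> tuple[int, ...]:
    """Chromatic candidate pool in a ``max_span``-semitone window centred on
    the source tessitura."""
    pitches = source.pitch_set if isinstance(source, TonePairAlphabet) else tuple(source)
    lo, hi = min(pitches), max(pitches)
    extra = max_span - (hi - lo)
    if extra < 0:
        raise ValueError(
            f"source span {hi - lo} exceeds max_span {max_span}; widen max_span"
        )
    start = lo - extra // 2
    return tuple(range(start, start + max_span + 1))


def candidate_mappings(
    source: TonePairAlphabet | Sequence[int],
    pool: Sequence[int] | None = None,
    limit: int = 200_000,
    seed: int = 0,
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[Mapping]:
    """Enumerate or sample injective mappings obeying the span constraint.

    If the number of injections from the source pitch set into ``pool`` is at
    most ``limit``, all of them are generated in deterministic (lexicographic)
    order and filtered by span; otherwise a seeded uniform sample of
    ``limit`` distinct span-feasible mappings is drawn.
    """
    src = tuple(source.pitch_set if isinstance(source, TonePairAlphabet) else sorted(source))
    pool_t = tuple(sorted(pool)) if pool is not None else default_target_pool(src, max_span)
    k, n = len(src), len(pool_t)
    if n < k:
        raise ValueError(f"pool of {n} pitches cannot host {k} source pitches")
    if not _span_feasible(pool_t, k, max_span):
        raise ValueError("span constraint unsatisfiable over this pool")

    total = math.perm(n, k)
    if total <= limit:
        out = [
            Mapping(src, tgt, pool_t)
            for tgt in permutations(pool_t, k)
            if max(tgt) - min(tgt) <= max_span
        ]
        return out

    rng = random.Random(seed)
    seen: set[tuple[int, ...]] = set()
    out = []
    attempts, max_attempts = 0, 200 * limit
    while len(out) < limit:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not draw {limit} span-feasible mappings "
                f"({len(out)} found); relax limit or span"
            )
        tgt = tuple(rng.sample(pool_t, k))
        if tgt in seen or max(tgt) - min(tgt) > max_span:
            continue
        seen.add(tgt)
        out.append(Mapping(src, tgt, pool_t))
    return out


def _span_feasible(pool: tuple[int, ...], k: int, max_span: int) -> bool:
    pool = tuple(sorted(pool))
    for i in range(len(pool)):
        window = [p for p in pool if pool[i] <= p <= pool[i] + max_span]
        if len(window) >= k:
            return True
    return False


def apply_mapping(
    m: Mapping, stimuli: Iterable[PitchSequence]
) -> list[PitchSequence]:
    """Pointwise pitch substitution; lengths and symbol structure preserved."""
    table = m.assignment
    out = []
    for s in stimuli:
        try:
            mapped = tuple(table[p] for p in s.pitches)
        except KeyError as exc:
            raise ValueError(f"pitch {exc.args[0]} not in mapping domain") from exc
        out.append(PitchSequence(mapped, source=s.source))
    return out


def _triple_indices(
    stimuli: Sequence[PitchSequence], src: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Index the three tones of every triple into the source pitch list, plus
    a weight vector giving each triple's contribution to the set profile
    (per-melody mean of triples, then unweighted mean over melodies)."""
    pos = {p: i for i, p in enumerate(src)}
    i1, i2, i3, w = [], [], [], []
    n_mel = len(stimuli)
    for s in stimuli:
        tones = s.pitches
        n_tr = len(tones) - 2
        if n_tr < 1:
            raise ValueError("all stimuli must have at least 3 tones")
        for a in range(n_tr):
            i1.append(pos[tones[a]])
            i2.append(pos[tones[a + 1]])
            i3.append(pos[tones[a + 2]])
            w.append(1.0 / (n_tr * n_mel))
    return (
        np.array(i1, dtype=np.intp),
        np.array(i2, dtype=np.intp),
        np.array(i3, dtype=np.intp),
        np.array(w),
    )


def score_mappings(
    cands: Sequence[Mapping],
    stimuli: Sequence[PitchSequence],
    cfg: ScoringConfig | None = None,
    chunk: int = 8192,
) -> list[MappingScore]:
    """Score every candidate mapping against the full stimulus set.

    Raw scores are the six mean Narmour factors of the mapped melody set;
    z-scores are taken per factor across the candidate population
    (population SD), and the competitive total is their unweighted sum.
    A factor with zero dispersion across candidates contributes z = 0.
    """
    if len(cands) < 2:
        raise ValueError("z-scores require at least 2 candidate mappings")
    cfg = cfg or ScoringConfig()
    src = cands[0].source_pitches
    if any(c.source_pitches != src for c in cands):
        raise ValueError("all candidates must share one source pitch set")
    i1, i2, i3, w = _triple_indices(stimuli, src)

    targets = np.array([c.target_pitches for c in cands], dtype=np.int64)
    raw = np.empty((len(cands), len(FACTORS)))
    for lo in range(0, len(cands), chunk):
        t = targets[lo : lo + chunk]
        p1, p2, p3 = t[:, i1], t[:, i2], t[:, i3]
        arrs = factor_arrays(p2 - p1, p3 - p2, cfg)
        for j, f in enumerate(FACTORS):
            raw[lo : lo + t.shape[0], j] = arrs[f] @ w

    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)  # population SD
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (raw - mu) / sd, 0.0)
    totals = z.sum(axis=1)

    n_pairs = i1.shape[0]
    return [
        MappingScore(
            mapping=c,
            raw=NarmourProfile(**dict(zip(FACTORS, raw[i].tolist())), n_pairs=n_pairs),
            z=tuple(z[i].tolist()),
            total=float(totals[i]),
        )
        for i, c in enumerate(cands)
    ]


def select_mapping(
    scores: Sequence[MappingScore], direction: str = "most_inconsistent"
) -> MappingScore:
    """Pick the extremal-total candidate; ties go to the earliest candidate.

    ``most_inconsistent`` minimizes the summed z (all factors are
    predictability scores, so low totals mean strong violation of melodic
    expectancy); ``most_consistent`` maximizes it.
    """
    if not scores:
        raise ValueError("no scores to select from")
    if direction not in ("most_consistent", "most_inconsistent"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "most_consistent" else -1.0
    best = max(range(len(scores)), key=lambda i: (sign * scores[i].total, -i))
    return scores[best]


def ranked_report(scores: Sequence[MappingScore], top: int | None = None) -> str:
    """Tab-separated ranked listing so the final pick can be made by hand,
    mirroring the manual selection step of the original procedure."""
    order = sorted(range(len(scores)), key=lambda i: scores[i].total)
    header = (
        ["rank", "total"]
        + [f"raw_{f}" for f in FACTORS]
        + [f"z_{f}" for f in FACTORS]
        + ["assignment"]
    )
    lines = ["\t".join(header)]
    for rank, i in enumerate(islice(order, top), start=1):
        s = scores[i]
        row = (
            [str(rank), f"{s.total:.4f}"]
            + [f"{v:.4f}" for v in s.raw.as_array()]
            + [f"{v:.4f}" for v in s.z]
            + [str(s.mapping)]
        )
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
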