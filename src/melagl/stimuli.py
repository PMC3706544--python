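"""Stimulus factory: ungrammatical classes, test-set assembly, manifests.

The test set mirrors the standard melodic AGL design: 17 old-grammatical
melodies (heard during learning), 16 new-grammatical melodies (test only),
and 33 ungrammatical melodies of five graded types, length-matched to the
grammatical melodies so duration carries no information:

1. entirely random terminal sequences;
2. every adjacent terminal bigram legal, but at least one trigram illegal
   (so only fragment knowledge up to pairs is preserved);
3. legal opening and closing anchors with a random interior;
4. hybrids joining half of an upper-pathway melody to half of a
   lower-pathway melody;
5. minimal perturbations — one adjacent swap or one deletion.

Every generated item is *certified* ungrammatical against the membership
oracle; generation rejection-samples under a seeded RNG with a bounded
number of retries.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping as TMapping, Sequence

import pandas as pd

from .grammar import (
    Grammar,
    GrammarError,
    PitchSequence,
    TerminalSequence,
    TonePairAlphabet,
    build_grammatical_sets,
    is_grammatical,
    realize_pitches,
    trace_pathway,
)
from .mapping import Mapping, apply_mapping

__all__ = [
    "Stimulus",
    "StimulusSet",
    "UNGRAM_COUNTS",
    "ngram_set",
    "gen_ungrammatical",
    "length_match",
    "assemble_test_set",
    "write_manifest",
    "read_manifest",
]

#: Ungrammatical item counts by error type 1..5.
UNGRAM_COUNTS = (6, 6, 7, 7, 7)

RETRY_BOUND = 1000


@dataclass(frozen=True)
class Stimulus:
    """One test or learning item with symbol-level and surface forms."""

    id: str
    category: str  # old_gram | new_gram | ungram
    error_type: int  # 0 for grammatical items, else 1..5
    seq: TerminalSequence
    pitches: PitchSequence

    @property
    def grammatical(self) -> bool:
        return self.category in ("old_gram", "new_gram")


@dataclass
class StimulusSet:
    """The 66-item test set plus the 3-block learning schedule."""

    old_gram: list[Stimulus]
    new_gram: list[Stimulus]
    ungram: dict[int, list[Stimulus]]
    learning_schedule: list[str] = field(default_factory=list)

    @property
    def test_set(self) -> list[Stimulus]:
        out = list(self.old_gram) + list(self.new_gram)
        for et in sorted(self.ungram):
            out.extend(self.ungram[et])
        return out

    @property
    def grammatical(self) -> list[Stimulus]:
        return list(self.old_gram) + list(self.new_gram)

    @property
    def ungrammatical(self) -> list[Stimulus]:
        return [s for et in sorted(self.ungram) for s in self.ungram[et]]

    def by_id(self, stim_id: str) -> Stimulus:
        for s in self.test_set:
            if s.id == stim_id:
                return s
        raise KeyError(stim_id)


def ngram_set(seqs: Iterable[TerminalSequence], n: int) -> set[tuple[str, ...]]:
    """All terminal n-grams occurring in any of the sequences."""
    grams: set[tuple[str, ...]] = set()
    for s in seqs:
        labs = s.labels
        for i in range(len(labs) - n + 1):
            grams.add(labs[i : i + n])
    return grams


def _certify(g: Grammar, labels: tuple[str, ...]) -> TerminalSequence | None:
    seq = TerminalSequence(labels)
    return None if is_grammatical(g, seq) else seq


def gen_ungrammatical(
    error_type: int,
    g: Grammar,
    gram_seqs: Sequence[TerminalSequence],
    target_len_pairs: int,
    rng: random.Random,
    anchor_len: int = 2,
) -> TerminalSequence:
    """Generate one certified-ungrammatical sequence of the requested type
    and length (in terminal pairs)."""
    if error_type not in (1, 2, 3, 4, 5):
        raise ValueError(f"error_type must be 1..5, got {error_type}")
    gen = {
        1: _gen_type1,
        2: _gen_type2,
        3: _gen_type3,
        4: _gen_type4,
        5: _gen_type5,
    }[error_type]
    for _ in range(RETRY_BOUND):
        labels = gen(g, gram_seqs, target_len_pairs, rng, anchor_len)
        if labels is None:
            continue
        seq = _certify(g, labels)
        if seq is not None:
            return seq
    raise RuntimeError(
        f"could not generate a certified type-{error_type} sequence of "
        f"{target_len_pairs} pairs within {RETRY_BOUND} retries"
    )


def _gen_type1(g, gram_seqs, length, rng, anchor_len):
    """Entirely random terminal sequence."""
    labels = sorted(g.terminal_labels)
    return tuple(rng.choice(labels) for _ in range(length))


def _gen_type2(g, gram_seqs, length, rng, anchor_len):
    """Bigram-legal random walk with at least one illegal trigram."""
    bigrams = ngram_set(gram_seqs, 2)
    trigrams = ngram_set(gram_seqs, 3)
    succ: dict[str, list[str]] = {}
    for a, b in bigrams:
        succ.setdefault(a, []).append(b)
    for v in succ.values():
        v.sort()
    starts = sorted(succ)
    out = [rng.choice(starts)]
    while len(out) < length:
        nxt = succ.get(out[-1])
        if not nxt:
            return None  # dead end; retry
        out.append(rng.choice(nxt))
    labels = tuple(out)
    has_illegal_tri = any(
        labels[i : i + 3] not in trigrams for i in range(len(labels) - 2)
    )
    return labels if has_illegal_tri else None


def _gen_type3(g, gram_seqs, length, rng, anchor_len):
    """Grammatical opening/closing anchors with random interior."""
    a = min(anchor_len, max(1, (length - 1) // 2))
    donors_pre = [s for s in gram_seqs if s.length_pairs >= a]
    donors_suf = [s for s in gram_seqs if s.length_pairs >= a]
    if not donors_pre or not donors_suf or length < 2 * a:
        return None
    prefix = rng.choice(donors_pre).labels[:a]
    suffix = rng.choice(donors_suf).labels[-a:]
    labels = sorted(g.terminal_labels)
    middle = tuple(rng.choice(labels) for _ in range(length - 2 * a))
    return prefix + middle + suffix


def _gen_type4(g, gram_seqs, length, rng, anchor_len):
    """First half from one pathway, second half from the other."""
    by_path: dict[str, list[TerminalSequence]] = {"upper": [], "lower": []}
    for s in gram_seqs:
        tag = trace_pathway(g, s)
        if tag in by_path:
            by_path[tag].append(s)
    h1 = math.ceil(length / 2)
    h2 = length - h1
    orientations = [("upper", "lower"), ("lower", "upper")]
    rng.shuffle(orientations)
    for first, second in orientations:
        pre = [s for s in by_path[first] if s.length_pairs >= h1]
        suf = [s for s in by_path[second] if s.length_pairs >= h2]
        if pre and suf:
            return rng.choice(pre).labels[:h1] + rng.choice(suf).labels[-h2:]
    return None


def _gen_type5(g, gram_seqs, length, rng, anchor_len):
    """One adjacent swap or one deletion applied to a grammatical donor."""
    swap_donors = [s for s in gram_seqs if s.length_pairs == length]
    del_donors = [s for s in gram_seqs if s.length_pairs == length + 1]
    use_swap = rng.random() < 0.5
    if use_swap and not swap_donors:
        use_swap = False
    if not use_swap and not del_donors:
        use_swap = True
    if use_swap:
        if not swap_donors:
            return None
        donor = rng.choice(swap_donors).labels
        # only swaps that change the sequence
        positions = [
            i for i in range(len(donor) - 1) if donor[i] != donor[i + 1]
        ]
        if not positions:
            return None
        i = rng.choice(positions)
        out = list(donor)
        out[i], out[i + 1] = out[i + 1], out[i]
        return tuple(out)
    donor = rng.choice(del_donors).labels
    i = rng.randrange(len(donor))
    return donor[:i] + donor[i + 1 :]


def length_match(
    gram_lengths: Sequence[int],
    slots: Sequence,
    rng: random.Random | None = None,
) -> dict:
    """Bijectively assign grammatical lengths (in pairs) to ungrammatical
    slots, so the resulting length multiset equals the grammatical one."""
    if len(gram_lengths) != len(slots):
        raise ValueError(
            f"{len(slots)} slots but {len(gram_lengths)} lengths to match"
        )
    lengths = list(gram_lengths)
    if rng is not None:
        rng.shuffle(lengths)
    return dict(zip(list(slots), lengths))


def assemble_test_set(
    g: Grammar,
    alphabet: TonePairAlphabet | None = None,
    mapping: Mapping | None = None,
    seed: int = 0,
    n_old: int = 17,
    n_new: int = 16,
    ungram_counts: Sequence[int] = UNGRAM_COUNTS,
    n_blocks: int = 3,
) -> StimulusSet:
    """Build the full length-matched test set and learning schedule.

    Grammatical sequences come from a seeded length-stratified draw on the
    grammar; ungrammatical items are generated per type with target lengths
    forming a permutation of the grammatical lengths; every melody is then
    realized as pitches (re-voiced through ``mapping`` when given).  The
    learning schedule is ``n_blocks`` seeded permutations of the
    old-grammatical items.
    """
    alphabet = alphabet or g.alphabet
    if alphabet is None:
        raise GrammarError("no tone-pair alphabet available")
    rng = random.Random(seed)
    old_seqs, new_seqs = build_grammatical_sets(g, alphabet, n_old, n_new, seed)
    gram_seqs = old_seqs + new_seqs

    slots = [
        (et, j)
        for et, count in zip(range(1, len(ungram_counts) + 1), ungram_counts)
        for j in range(count)
    ]
    gram_lengths = [s.length_pairs for s in gram_seqs]
    assignment = length_match(gram_lengths, slots, rng)

    seen: set[tuple[str, ...]] = {s.labels for s in gram_seqs}
    ungram: dict[int, list[TerminalSequence]] = {et: [] for et in range(1, len(ungram_counts) + 1)}
    for (et, j), target in assignment.items():
        for _ in range(RETRY_BOUND):
            seq = gen_ungrammatical(et, g, gram_seqs, target, rng)
            if seq.labels not in seen:
                break
        else:
            raise RuntimeError(
                f"could not generate a distinct type-{et} sequence of {target} pairs"
            )
        seen.add(seq.labels)
        ungram[et].append(seq)

    def realize(seq: TerminalSequence) -> PitchSequence:
        ps = realize_pitches(seq, alphabet)
        return apply_mapping(mapping, [ps])[0] if mapping is not None else ps

    old = [
        Stimulus(f"old{i + 1:02d}", "old_gram", 0, s, realize(s))
        for i, s in enumerate(old_seqs)
    ]
    new = [
        Stimulus(f"new{i + 1:02d}", "new_gram", 0, s, realize(s))
        for i, s in enumerate(new_seqs)
    ]
    ungram_stims = {
        et: [
            Stimulus(f"e{et}_{i + 1:02d}", "ungram", et, s, realize(s))
            for i, s in enumerate(seqs)
        ]
        for et, seqs in ungram.items()
    }

    schedule: list[str] = []
    old_ids = [s.id for s in old]
    for _ in range(n_blocks):
        block = old_ids[:]
        rng.shuffle(block)
        schedule.extend(block)

    return StimulusSet(old, new, ungram_stims, schedule)


def write_manifest(ss: StimulusSet, path: str | Path) -> pd.DataFrame:
    """Write the stimulus manifest TSV (plus the learning schedule as a
    comment header line) and return it as a DataFrame."""
    rows = [
        {
            "id": s.id,
            "category": s.category,
            "error_type": s.error_type,
            "label_sequence": "-".join(s.seq.labels),
            "pitch_csv": ",".join(str(p) for p in s.pitches.pitches),
            "n_tones": len(s.pitches),
        }
        for s in ss.test_set
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# schedule: " + ",".join(ss.learning_schedule) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return df


def read_manifest(path: str | Path) -> StimulusSet:
    """Rebuild a StimulusSet from a manifest written by :func:`write_manifest`."""
    path = Path(path)
    schedule: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# schedule:"):
            payload = first.split(":", 1)[1].strip()
            schedule = payload.split(",") if payload else []
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    old, new, ungram = [], [], {}
    for _, row in df.iterrows():
        seq = TerminalSequence(tuple(str(row["label_sequence"]).split("-")))
        pitches = PitchSequence(
            tuple(int(p) for p in str(row["pitch_csv"]).split(",")), source=seq
        )
        stim = Stimulus(
            str(row["id"]), str(row["category"]), int(row["error_type"]), seq, pitches
        )
        if stim.category == "old_gram":
            old.append(stim)
        elif stim.category == "new_gram":
            new.append(stim)
        else:
            ungram.setdefault(stim.error_type, []).append(stim)
    return StimulusSet(old, new, ungram, schedule)
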