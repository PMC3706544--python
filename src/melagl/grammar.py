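"""Finite-state grammar over terminal tone pairs.

A melody grammar in the artificial-grammar-learning tradition: a (possibly
nondeterministic) finite-state machine whose alphabet is a set of *tone
pairs*.  Each terminal emits two MIDI pitches, so a sequence of k terminals
realizes a melody of 2k tones.  The module covers loading and validating a
grammar description, enumerating and testing terminal sequences, realizing
them as pitch sequences, and drawing the old-/new-grammatical stimulus sets
used in the learning and testing phases.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "TonePair",
    "TonePairAlphabet",
    "Grammar",
    "TerminalSequence",
    "PitchSequence",
    "GrammarError",
    "load_grammar",
    "enumerate_sequences",
    "is_grammatical",
    "trace_pathway",
    "realize_pitches",
    "build_grammatical_sets",
]


class GrammarError(ValueError):
    """Malformed or inconsistent grammar description."""


@dataclass(frozen=True)
class TonePair:
    """A terminal symbol: an ordered pair of MIDI pitches with a short label."""

    first: int
    second: int
    label: str

    def __post_init__(self) -> None:
        for p in (self.first, self.second):
            if not (0 <= p <= 127):
                raise GrammarError(f"pitch {p} outside MIDI range 0-127")
        if not self.label:
            raise GrammarError("terminal label must be non-empty")

    @property
    def pitches(self) -> tuple[int, int]:
        return (self.first, self.second)


@dataclass(frozen=True)
class TonePairAlphabet:
    """Ordered collection of tone pairs with unique labels."""

    pairs: tuple[TonePair, ...]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.pairs]
        if len(set(labels)) != len(labels):
            raise GrammarError("duplicate terminal labels in alphabet")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.pairs)

    @property
    def pitch_set(self) -> tuple[int, ...]:
        """Sorted distinct pitches occurring in any tone pair."""
        return tuple(sorted({p for pair in self.pairs for p in pair.pitches}))

    @property
    def span(self) -> int:
        """Tessitura of the alphabet in semitones (max - min pitch)."""
        ps = self.pitch_set
        return ps[-1] - ps[0]

    def __getitem__(self, label: str) -> TonePair:
        for p in self.pairs:
            if p.label == label:
                return p
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(p.label == label for p in self.pairs)


@dataclass(frozen=True)
class TerminalSequence:
    """An ordered sequence of terminal labels (a melody at the symbol level)."""

    labels: tuple[str, ...]

    @property
    def length_pairs(self) -> int:
        return len(self.labels)

    @property
    def length_tones(self) -> int:
        return 2 * len(self.labels)

    def __str__(self) -> str:
        return "".join(self.labels) if all(len(l) == 1 for l in self.labels) else "-".join(self.labels)


@dataclass(frozen=True)
class PitchSequence:
    """A realized melody: MIDI note numbers, with its symbol-level source."""

    pitches: tuple[int, ...]
    source: TerminalSequence | None = None

    def __len__(self) -> int:
        return len(self.pitches)

    @property
    def span(self) -> int:
        return max(self.pitches) - min(self.pitches)

    def intervals(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in zip(self.pitches, self.pitches[1:]))


@dataclass(frozen=True)
class Grammar:
    """Finite-state machine over terminal labels.

    ``transitions`` is a set of ``(from_state, label, to_state)`` triples;
    nondeterminism is allowed.  ``pathway_tags`` optionally assigns states to
    the named branches (``upper`` / ``lower``) of the machine, with untagged
    states treated as shared; the tags drive the cross-pathway hybrid error
    type.  ``alphabet`` carries the terminal tone pairs when the description
    provides them.
    """

    states: frozenset[str]
    start: str
    accepts: frozenset[str]
    transitions: tuple[tuple[str, str, str], ...]
    pathway_tags: Mapping[str, str] | None = None
    alphabet: TonePairAlphabet | None = None
    _delta: dict[tuple[str, str], frozenset[str]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.start not in self.states:
            raise GrammarError(f"start state {self.start!r} not in states")
        missing = self.accepts - self.states
        if missing:
            raise GrammarError(f"accept states not in states: {sorted(missing)}")
        for src, lab, dst in self.transitions:
            if src not in self.states:
                raise GrammarError(f"transition from unknown state {src!r}")
            if dst not in self.states:
                raise GrammarError(f"transition to unknown state {dst!r}")
            if self.alphabet is not None and lab not in self.alphabet:
                raise GrammarError(f"transition label {lab!r} not in alphabet")
        if self.pathway_tags:
            bad = {t for t in self.pathway_tags.values() if t not in ("upper", "lower", "shared")}
            if bad:
                raise GrammarError(f"unknown pathway tags: {sorted(bad)}")
        delta: dict[tuple[str, str], set[str]] = {}
        for src, lab, dst in self.transitions:
            delta.setdefault((src, lab), set()).add(dst)
        object.__setattr__(
            self, "_delta", {k: frozenset(v) for k, v in delta.items()}
        )
        if not self._accept_reachable():
            raise GrammarError("no accept state reachable from start")

    @property
    def terminal_labels(self) -> frozenset[str]:
        return frozenset(lab for _, lab, _ in self.transitions)

    def step(self, states: Iterable[str], label: str) -> frozenset[str]:
        out: set[str] = set()
        for s in states:
            out |= self._delta.get((s, label), frozenset())
        return frozenset(out)

    def _accept_reachable(self) -> bool:
        seen = {self.start}
        queue = deque([self.start])
        while queue:
            s = queue.popleft()
            if s in self.accepts:
                return True
            for (src, _), dsts in self._delta.items():
                if src == s:
                    for d in dsts:
                        if d not in seen:
                            seen.add(d)
                            queue.append(d)
        return False


def load_grammar(doc: str | Path | Mapping) -> Grammar:
    """Parse a structured grammar description (YAML text, path, or mapping).

    Expected keys: ``states``, ``start``, ``accepts``, ``transitions`` (list
    of ``[from, label, to]``), and optionally ``terminals`` (label ->
    ``[pitch, pitch]``) and ``pathways`` (tag -> list of states).
    """
    if isinstance(doc, Mapping):
        data = doc
    else:
        text = Path(doc).read_text() if isinstance(doc, Path) else doc
        # Bare strings that are actually file paths are common CLI input.
        if isinstance(doc, str) and "\n" not in doc and Path(doc).exists():
            text = Path(doc).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise GrammarError(f"could not parse grammar document: {exc}") from exc
    if not isinstance(data, Mapping):
        raise GrammarError("grammar document must be a mapping")
    for key in ("states", "start", "accepts", "transitions"):
        if key not in data:
            raise GrammarError(f"grammar document missing key {key!r}")

    transitions = []
    for t in data["transitions"]:
        if len(t) != 3:
            raise GrammarError(f"transition {t!r} must be [from, label, to]")
        transitions.append((str(t[0]), str(t[1]), str(t[2])))

    alphabet = None
    if "terminals" in data and data["terminals"]:
        pairs = tuple(
            TonePair(int(v[0]), int(v[1]), str(lab))
            for lab, v in data["terminals"].items()
        )
        alphabet = TonePairAlphabet(pairs)

    tags: dict[str, str] | None = None
    if "pathways" in data and data["pathways"]:
        tags = {}
        for tag, states in data["pathways"].items():
            for s in states:
                tags[str(s)] = str(tag)

    return Grammar(
        states=frozenset(str(s) for s in data["states"]),
        start=str(data["start"]),
        accepts=frozenset(str(s) for s in data["accepts"]),
        transitions=tuple(transitions),
        pathway_tags=tags,
        alphabet=alphabet,
    )


def enumerate_sequences(g: Grammar, max_pairs: int) -> list[TerminalSequence]:
    """All accepting label sequences of at most ``max_pairs`` terminals.

    Deterministic lexicographic order; duplicates (from nondeterministic
    paths) removed.  Cycles are bounded by ``max_pairs``.
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    labels = sorted(g.terminal_labels)
    found: set[tuple[str, ...]] = set()
    # BFS over NFA state-sets keyed by the label prefix.
    frontier: dict[tuple[str, ...], frozenset[str]] = {(): frozenset({g.start})}
    if g.start in g.accepts:
        found.add(())
    for _ in range(max_pairs):
        nxt: dict[tuple[str, ...], frozenset[str]] = {}
        for prefix, states in frontier.items():
            for lab in labels:
                dsts = g.step(states, lab)
                if dsts:
                    seq = prefix + (lab,)
                    nxt[seq] = dsts
                    if dsts & g.accepts:
                        found.add(seq)
        frontier = nxt
        if not frontier:
            break
    nonempty = sorted(s for s in found if s)
    return [TerminalSequence(s) for s in nonempty]


def is_grammatical(g: Grammar, seq: TerminalSequence | Sequence[str]) -> bool:
    """Membership oracle: does ``seq`` label an accepting path of ``g``?"""
    labels = seq.labels if isinstance(seq, TerminalSequence) else tuple(seq)
    known = g.terminal_labels
    for lab in labels:
        if lab not in known:
            raise GrammarError(f"unknown terminal label {lab!r}")
    states: frozenset[str] = frozenset({g.start})
    for lab in labels:
        states = g.step(states, lab)
        if not states:
            return False
    return bool(states & g.accepts)


def trace_pathway(g: Grammar, seq: TerminalSequence) -> str:
    """Classify an accepting sequence by the pathway tags of its states.

    Returns ``upper``, ``lower``, ``mixed`` (both tags touched) or ``shared``
    (no tagged state on any accepting path).  Uses the first accepting path
    in depth-first label order.
    """
    if g.pathway_tags is None:
        raise GrammarError("grammar has no pathway tags")

    def dfs(state: str, i: int, visited: tuple[str, ...]) -> tuple[str, ...] | None:
        if i == len(seq.labels):
            return visited if state in g.accepts else None
        for dst in sorted(g._delta.get((state, seq.labels[i]), ())):
            res = dfs(dst, i + 1, visited + (dst,))
            if res is not None:
                return res
        return None

    path = dfs(g.start, 0, (g.start,))
    if path is None:
        raise GrammarError("sequence is not grammatical; no pathway to trace")
    tags = {g.pathway_tags.get(s, "shared") for s in path} - {"shared"}
    if tags == {"upper"}:
        return "upper"
    if tags == {"lower"}:
        return "lower"
    return "mixed" if tags else "shared"


def realize_pitches(
    seq: TerminalSequence, alphabet: TonePairAlphabet
) -> PitchSequence:
    """Concatenate each terminal's two pitches, order preserved."""
    pitches: list[int] = []
    for lab in seq.labels:
        if lab not in alphabet:
            raise GrammarError(f"label {lab!r} not in alphabet")
        pitches.extend(alphabet[lab].pitches)
    return PitchSequence(tuple(pitches), source=seq)


def build_grammatical_sets(
    g: Grammar,
    alphabet: TonePairAlphabet,
    n_old: int,
    n_new: int,
    seed: int,
    *,
    max_pairs: int = 15,
    min_tones: int = 8,
    max_tones: int = 30,
) -> tuple[list[TerminalSequence], list[TerminalSequence]]:
    """Draw disjoint old-/new-grammatical sequence sets from the grammar.

    Sequences are enumerated up to ``max_pairs`` terminals and restricted to
    the melody length window (8-30 tones by default).  A seeded,
    length-stratified draw picks ``n_old + n_new`` sequences; the old/new
    split then sorts by length and alternates assignment (seeded shuffle
    within equal lengths) so length carries no information about old vs new.
    """
    pool = [
        s
        for s in enumerate_sequences(g, max_pairs)
        if min_tones <= s.length_tones <= max_tones
    ]
    need = n_old + n_new
    if len(pool) < need:
        raise GrammarError(
            f"grammar yields only {len(pool)} sequences in the length window; "
            f"{need} required"
        )
    rng = random.Random(seed)

    # Length-stratified draw: cycle through lengths, picking one random
    # remaining sequence per length, so all lengths stay represented.
    by_len: dict[int, list[TerminalSequence]] = {}
    for s in pool:
        by_len.setdefault(s.length_pairs, []).append(s)
    for seqs in by_len.values():
        rng.shuffle(seqs)
    chosen: list[TerminalSequence] = []
    lengths = sorted(by_len)
    while len(chosen) < need:
        progressed = False
        for ln in lengths:
            if by_len[ln] and len(chosen) < need:
                chosen.append(by_len[ln].pop())
                progressed = True
        if not progressed:  # pragma: no cover - guarded by len(pool) check
            break

    # Old/new split: sort by length, alternate, seeded tie order.
    rng.shuffle(chosen)
    chosen.sort(key=lambda s: s.length_pairs)
    old: list[TerminalSequence] = []
    new: list[TerminalSequence] = []
    for i, s in enumerate(chosen):
        (old if i % 2 == 0 else new).append(s)
    # Alternation gives ceil/floor sizes; trim to the requested split.
    while len(old) > n_old:
        new.append(old.pop())
    while len(new) > n_new:
        old.append(new.pop())
    return old, new
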