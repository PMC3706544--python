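"""Minimal Standard MIDI File (format 0) writer and reader.

Stimuli are isochronous monophonic melodies: every note starts at a fixed
inter-onset interval (IOI) and is held until the next onset.  That needs
only a tiny corner of the SMF spec, written here directly: one track, a set
tempo meta event, and note on/off pairs.  The reader exists so rendered
files can be verified (onsets, pitches, velocities) without external tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .grammar import PitchSequence

__all__ = ["RenderSpec", "render_midi", "read_midi"]

_TPQ = 480  # ticks per quarter note; one note occupies one quarter


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters: IOI in ms, MIDI velocity, program number."""

    ioi_ms: int = 330
    velocity: int = 100
    program: int = 0  # acoustic grand piano

    def __post_init__(self) -> None:
        if self.ioi_ms <= 0:
            raise ValueError("ioi_ms must be positive")
        if not (1 <= self.velocity <= 127):
            raise ValueError("velocity must be in 1..127")
        if not (0 <= self.program <= 127):
            raise ValueError("program must be in 0..127")


def _vlq(value: int) -> bytes:
    """Variable-length quantity encoding."""
    if value < 0:
        raise ValueError("negative delta time")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def render_midi(
    s: PitchSequence | Sequence[int],
    spec: RenderSpec | None = None,
    path: str | Path | None = None,
) -> bytes:
    """Render a melody to SMF format 0 bytes; optionally write to ``path``.

    Note *k* (0-based) onsets at ``k * ioi_ms`` milliseconds and lasts one
    IOI; all notes carry ``spec.velocity``.  The tempo meta event is set to
    ``ioi_ms`` milliseconds per quarter note so that one quarter (480 ticks)
    equals one IOI exactly.
    """
    spec = spec or RenderSpec()
    pitches = s.pitches if isinstance(s, PitchSequence) else tuple(s)
    if not pitches:
        raise ValueError("cannot render an empty melody")
    for p in pitches:
        if not (0 <= p <= 127):
            raise ValueError(f"pitch {p} outside MIDI range")

    track = bytearray()
    tempo_us = spec.ioi_ms * 1000  # microseconds per quarter note
    track += _vlq(0) + bytes([0xFF, 0x51, 0x03]) + tempo_us.to_bytes(3, "big")
    track += _vlq(0) + bytes([0xC0, spec.program])
    for p in pitches:
        track += _vlq(0) + bytes([0x90, p, spec.velocity])  # note on
        track += _vlq(_TPQ) + bytes([0x80, p, 0])  # note off one IOI later
    track += _vlq(0) + bytes([0xFF, 0x2F, 0x00])  # end of track

    header = (
        b"MThd"
        + (6).to_bytes(4, "big")
        + (0).to_bytes(2, "big")  # format 0
        + (1).to_bytes(2, "big")  # one track
        + _TPQ.to_bytes(2, "big")
    )
    data = header + b"MTrk" + len(track).to_bytes(4, "big") + bytes(track)
    if path is not None:
        Path(path).write_bytes(data)
    return data


def _read_vlq(data: bytes, i: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[i]
        i += 1
        value = (value << 7) | (b & 0x7F)
        if not (b & 0x80):
            return value, i


def read_midi(source: bytes | str | Path) -> list[dict]:
    """Parse an SMF-0 file back into note events.

    Returns one dict per note with ``pitch``, ``velocity``, ``onset_ms`` and
    ``offset_ms``, using the tempo events in the file to convert ticks.
    """
    data = Path(source).read_bytes() if not isinstance(source, bytes) else source
    if data[:4] != b"MThd":
        raise ValueError("not a standard MIDI file")
    tpq = int.from_bytes(data[12:14], "big")
    i = 14
    if data[i : i + 4] != b"MTrk":
        raise ValueError("expected a single MTrk chunk")
    length = int.from_bytes(data[i + 4 : i + 8], "big")
    i += 8
    end = i + length

    tempo_us = 500_000
    tick = 0
    notes: list[dict] = []
    open_notes: dict[int, dict] = {}
    running_status = 0

    def ms(ticks: int) -> float:
        return ticks * tempo_us / tpq / 1000.0

    while i < end:
        delta, i = _read_vlq(data, i)
        tick += delta
        status = data[i]
        if status & 0x80:
            i += 1
            if status < 0xF0:
                running_status = status
        else:
            status = running_status
        if status == 0xFF:  # meta
            meta_type = data[i]
            ln, i2 = _read_vlq(data, i + 1)
            payload = data[i2 : i2 + ln]
            if meta_type == 0x51:
                tempo_us = int.from_bytes(payload, "big")
            i = i2 + ln
        elif status & 0xF0 == 0x90:
            pitch, vel = data[i], data[i + 1]
            i += 2
            if vel > 0:
                open_notes[pitch] = {
                    "pitch": pitch,
                    "velocity": vel,
                    "onset_ms": ms(tick),
                }
            else:
                _close(open_notes, notes, pitch, ms(tick))
        elif status & 0xF0 == 0x80:
            pitch = data[i]
            i += 2
            _close(open_notes, notes, pitch, ms(tick))
        elif status & 0xF0 in (0xC0, 0xD0):
            i += 1
        else:
            i += 2
    return sorted(notes, key=lambda n: n["onset_ms"])


def _close(open_notes: dict, notes: list, pitch: int, off_ms: float) -> None:
    ev = open_notes.pop(pitch, None)
    if ev is not None:
        ev["offset_ms"] = off_ms
        notes.append(ev)
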