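"""Minimal Standard MIDI File (format 0) reader/writer.

Covers exactly the dialect used for target timelines: a single track at a
fixed pulses-per-quarter resolution, one tempo meta-event, and note-on /
note-off pairs on one channel. Running status is handled on read; writes
never use it.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass
from typing import BinaryIO, Union

PPQ = 480
NOTE_DURATION_TICKS = PPQ // 4
_CHANNEL = 9  # general-MIDI percussion channel
_VELOCITY = 100


class MidiFormatError(ValueError):
    """Raised when a file is not the single-track two-note dialect."""


@dataclass(frozen=True)
class NoteEvent:
    tick: int
    note: int


def _encode_varint(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _read_varint(buf: io.BytesIO) -> int:
    value = 0
    for _ in range(4):
        raw = buf.read(1)
        if not raw:
            raise MidiFormatError("truncated variable-length quantity")
        byte = raw[0]
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value
    raise MidiFormatError("variable-length quantity longer than 4 bytes")


def write_smf0(
    dest: Union[str, BinaryIO],
    notes: list[NoteEvent],
    us_per_quarter: int,
    ppq: int = PPQ,
) -> None:
    """Write note events (sorted by tick) as a format-0 file."""
    track = bytearray()
    track += _encode_varint(0)
    track += bytes([0xFF, 0x51, 0x03]) + us_per_quarter.to_bytes(3, "big")

    # Interleave note-offs so delta times stay non-negative.
    pending: list[tuple[int, int, int]] = []  # (tick, status, note)
    for ev in sorted(notes, key=lambda e: e.tick):
        pending.append((ev.tick, 0x90 | _CHANNEL, ev.note))
        pending.append((ev.tick + NOTE_DURATION_TICKS, 0x80 | _CHANNEL, ev.note))
    pending.sort(key=lambda t: (t[0], t[1]))

    cursor = 0
    for tick, status, note in pending:
        track += _encode_varint(tick - cursor)
        track += bytes([status, note, _VELOCITY if status & 0xF0 == 0x90 else 0])
        cursor = tick
    track += _encode_varint(0) + bytes([0xFF, 0x2F, 0x00])

    payload = (
        b"MThd"
        + struct.pack(">IHHH", 6, 0, 1, ppq)
        + b"MTrk"
        + struct.pack(">I", len(track))
        + bytes(track)
    )
    if isinstance(dest, (str, bytes)):
        with open(dest, "wb") as fh:
            fh.write(payload)
    else:
        dest.write(payload)


def read_smf0(source: Union[str, BinaryIO]) -> tuple[int, int, list[NoteEvent]]:
    """Read a format-0 file; returns (ppq, us_per_quarter, note-on events)."""
    if isinstance(source, (str, bytes)):
        with open(source, "rb") as fh:
            data = fh.read()
    else:
        data = source.read()
    if len(data) < 14 or data[:4] != b"MThd":
        raise MidiFormatError("missing MThd header")
    header_len, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if header_len != 6:
        raise MidiFormatError(f"unexpected header length {header_len}")
    if fmt != 0 or ntrks != 1:
        raise MidiFormatError(f"expected single-track format 0, got format {fmt} with {ntrks} tracks")
    if division & 0x8000:
        raise MidiFormatError("SMPTE time division is not supported")

    offset = 14
    if data[offset : offset + 4] != b"MTrk":
        raise MidiFormatError("missing MTrk chunk")
    (track_len,) = struct.unpack(">I", data[offset + 4 : offset + 8])
    buf = io.BytesIO(data[offset + 8 : offset + 8 + track_len])

    us_per_quarter = 500_000  # MIDI default: 120 bpm
    notes: list[NoteEvent] = []
    tick = 0
    status = 0
    while True:
        head = buf.read(1)
        if not head:
            break
        buf.seek(-1, io.SEEK_CUR)
        tick += _read_varint(buf)
        byte = buf.read(1)[0]
        if byte == 0xFF:
            meta_type = buf.read(1)[0]
            length = _read_varint(buf)
            body = buf.read(length)
            if meta_type == 0x51:
                us_per_quarter = int.from_bytes(body, "big")
            elif meta_type == 0x2F:
                break
            continue
        if byte in (0xF0, 0xF7):  # sysex
            buf.read(_read_varint(buf))
            continue
        if byte & 0x80:
            status = byte
            first = buf.read(1)[0]
        else:  # running status
            first = byte
        kind = status & 0xF0
        n_data = 1 if kind in (0xC0, 0xD0) else 2
        rest = buf.read(n_data - 1)
        if kind == 0x90 and rest and rest[0] > 0:
            notes.append(NoteEvent(tick=tick, note=first))
    return division, us_per_quarter, notes
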