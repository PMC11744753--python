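"""Clock-time helpers.

All times in this package are naive local clock times expressed as seconds
since local midnight. Durations that cross midnight (a sleep recording
starting at 23:00) are handled on a *linear* axis anchored at the recording
start; only at the reporting boundary are values folded back onto [0, 24 h).
"""

from __future__ import annotations

DAY_S = 86400


def parse_clock(text: str) -> int:
    """Parse ``"HH:MM"`` or ``"HH:MM:SS"`` into seconds since midnight."""
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"not a clock time: {text!r}")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"clock time out of range: {text!r}")
    return h * 3600 + m * 60 + s


def format_clock(seconds: float, with_seconds: bool = False) -> str:
    """Format seconds-since-midnight as ``HH:MM`` (folded into one day)."""
    s = int(round(seconds)) % DAY_S
    h, rem = divmod(s, 3600)
    m, sec = divmod(rem, 60)
    if with_seconds:
        return f"{h:02d}:{m:02d}:{sec:02d}"
    return f"{h:02d}:{m:02d}"
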