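"""ISO 8601 date handling with reduced precision.

Field trials routinely record dates at year or month granularity, so the
model accepts the reduced-precision forms ``YYYY``, ``YYYY-MM``,
``YYYY-MM-DD`` and full timestamps (with optional zone offset or ``Z``).
Values are kept as the strings the user wrote; parsing is only used for
validation and ordering.
"""

from __future__ import annotations

import re
from datetime import date, datetime

_YEAR_RE = re.compile(r"^\d{4}$")
_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


def parse_iso8601(text: str) -> datetime | None:
    """Parse an ISO 8601 string at any supported precision.

    Returns a ``datetime`` (missing components default to the earliest
    instant: January, day 1, midnight) or ``None`` if the string is not a
    valid ISO 8601 date / timestamp. Impossible calendar dates (such as
    June 31) are rejected.
    """
    if not isinstance(text, str) or not text.strip():
        return None
    text = text.strip()
    if _YEAR_RE.match(text):
        return datetime(int(text), 1, 1)
    m = _MONTH_RE.match(text)
    if m:
        year, month = int(m.group(1)), int(m.group(2))
        if 1 <= month <= 12:
            return datetime(year, month, 1)
        return None
    try:
        if "T" in text or " " in text:
            parsed = datetime.fromisoformat(text.replace("Z", "+00:00"))
            # strip the zone so reduced-precision values stay comparable
            return parsed.replace(tzinfo=None)
        d = date.fromisoformat(text)
        return datetime(d.year, d.month, d.day)
    except ValueError:
        return None


def is_iso8601(text: str) -> bool:
    """Whether *text* is a valid ISO 8601 date or timestamp."""
    return parse_iso8601(text) is not None
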