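"""Date-offset de-identification.

Real calendar dates are direct quasi-identifiers, so instead of storing
them, each subject gets one *base date* kept only in encrypted form, and
every other date is stored as a signed whole-day offset from that base.
Offsets alone preserve every between-date interval exactly — enough for
most time-to-event analysis — while revealing no calendar position. A key
holder reconstructs true dates by decrypting the base and adding offsets.

The base date is serialized as ISO-8601 text before encryption; since a
wrong key almost never decrypts to a parseable date, the parse doubles as a
wrong-key detector. Dates are proleptic-Gregorian calendar dates, not
instants: no time-of-day, no timezones. The base itself need not be a real
event date — any date works, and the choice does not affect decoding.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import IntegrityError, ValidationError
from .fieldcrypt import decrypt_field, encrypt_field
from .keyring import EncryptionKey

__all__ = ["DateOffsetRecord", "encode_dates", "decode_dates"]


@dataclass(frozen=True)
class DateOffsetRecord:
    """One encrypted base date plus named signed day-offsets."""

    base_cipher: str
    offsets: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, off in self.offsets.items():
            # bool is an int subclass; reject it explicitly
            if not isinstance(off, int) or isinstance(off, bool):
                raise ValidationError(f"offset {name!r} must be an integer, got {off!r}")


def _as_date(value: object, name: str) -> dt.date:
    if isinstance(value, dt.datetime):  # a datetime is not a calendar date
        raise ValidationError(f"{name} must be a calendar date, not a datetime")
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        try:
            return dt.date.fromisoformat(value)
        except ValueError as exc:
            raise ValidationError(f"{name} is not a valid ISO-8601 date: {value!r}") from exc
    raise ValidationError(f"{name} must be a date or ISO-8601 text, got {type(value).__name__}")


def encode_dates(
    dates: Mapping[str, dt.date | str],
    base: dt.date | str,
    key: EncryptionKey,
    nonce: Optional[bytes] = None,
) -> DateOffsetRecord:
    """Replace calendar dates by day-offsets from an encrypted base date.

    Offsets are exact signed whole days (negative when a date precedes the
    base). *nonce* is test plumbing, as in :func:`~phicrypt.fieldcrypt.encrypt_field`.
    """
    base_date = _as_date(base, "base")
    offsets = {
        name: (_as_date(value, name) - base_date).days for name, value in dates.items()
    }
    return DateOffsetRecord(
        base_cipher=encrypt_field(base_date.isoformat(), key, nonce),
        offsets=offsets,
    )


def decode_dates(record: DateOffsetRecord, key: EncryptionKey) -> dict[str, dt.date]:
    """Reconstruct true calendar dates: decrypted base plus each offset."""
    base_text = decrypt_field(record.base_cipher, key)
    try:
        base_date = dt.date.fromisoformat(base_text)
    except ValueError as exc:
        raise IntegrityError(
            "decrypted base is not a calendar date (wrong key or corrupted container)"
        ) from exc
    return {
        name: base_date + dt.timedelta(days=off) for name, off in record.offsets.items()
    }
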