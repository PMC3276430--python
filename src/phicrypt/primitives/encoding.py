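"""Base64 codec (RFC 4648, standard alphabet, mandatory padding).

Implemented over numpy sextet arithmetic; the test suite cross-checks it
against the platform ``base64`` module on the published vectors and random
inputs.
"""

from __future__ import annotations

import numpy as np

from ..errors import FormatError

__all__ = ["b64_encode", "b64_decode"]

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789+/"
_ENC = np.frombuffer(_ALPHABET.encode("ascii"), dtype=np.uint8)
_DEC = np.full(256, -1, dtype=np.int16)
for _i, _c in enumerate(_ALPHABET.encode("ascii")):
    _DEC[_c] = _i


def b64_encode(data: bytes) -> str:
    """Encode *data* as padded standard-alphabet Base64 text."""
    data = bytes(data)
    if not data:
        return ""
    pad = (3 - len(data) % 3) % 3
    buf = np.frombuffer(data + b"\x00" * pad, dtype=np.uint8).reshape(-1, 3).astype(np.uint32)
    triples = (buf[:, 0] << 16) | (buf[:, 1] << 8) | buf[:, 2]
    sextets = np.stack(
        [(triples >> 18) & 0x3F, (triples >> 12) & 0x3F, (triples >> 6) & 0x3F, triples & 0x3F],
        axis=1,
    )
    out = _ENC[sextets.ravel()].tobytes().decode("ascii")
    if pad:
        out = out[:-pad] + "=" * pad
    return out


def b64_decode(text: str) -> bytes:
    """Decode padded standard-alphabet Base64 text.

    Raises
    ------
    FormatError
        If the length is not a multiple of 4, padding is malformed, or a
        character falls outside the RFC 4648 standard alphabet.
    """
    if not isinstance(text, str):
        raise FormatError("Base64 input must be text")
    if text == "":
        return b""
    if len(text) % 4 != 0:
        raise FormatError("Base64 length must be a multiple of 4")
    pad = len(text) - len(text.rstrip("="))
    if pad > 2 or "=" in text[: len(text) - pad]:
        raise FormatError("malformed Base64 padding")
    body = text[: len(text) - pad] + "A" * pad
    try:
        raw = body.encode("ascii")
    except UnicodeEncodeError as exc:
        raise FormatError("non-ASCII character in Base64 input") from exc
    codes = _DEC[np.frombuffer(raw, dtype=np.uint8)]
    if (codes < 0).any():
        raise FormatError("character outside the Base64 alphabet")
    sextets = codes.astype(np.uint32).reshape(-1, 4)
    triples = (sextets[:, 0] << 18) | (sextets[:, 1] << 12) | (sextets[:, 2] << 6) | sextets[:, 3]
    buf = np.stack([(triples >> 16) & 0xFF, (triples >> 8) & 0xFF, triples & 0xFF], axis=1)
    out = buf.astype(np.uint8).tobytes()
    if pad:
        # canonical-form check (RFC 4648 §3.5): bits beyond the final octet
        # must be zero, so that distinct texts never decode identically
        if out[-pad:] != b"\x00" * pad:
            raise FormatError("non-canonical Base64: non-zero trailing pad bits")
        out = out[: len(out) - pad]
    return out
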