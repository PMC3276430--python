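"""Passcodes, keys, verification hashes, key wrapping and escrow.

The trust model: a human-memorable passcode is expanded to a 256-bit AES key
by a single SHA-256; the server never sees the passcode or the key, only a
*verification hash* — the SHA-256 of the key's lowercase-hex form — which
lets a client confirm a typed passcode is correct before decrypting, without
giving the server any decryption capability.

Two hashing conventions matter and are easy to confuse:

* the key is the digest of the **UTF-8 passcode** (NFC-normalized);
* the verification hash is the digest of the **ASCII hex string** of the
  key, not of its raw 32 bytes.

The second convention is required for interoperability: hashing the raw
digest bytes yields a different (wrong) verification hash.

The two-tier scheme: data is encrypted under a per-participant key; that
key's hex form is itself encrypted ("wrapped") under a site-wide key, so a
participant's passcode or the site's passcode each independently unlock the
record. The server stores only the two verification hashes and the wrapped
key — none of which reveal key material.

Deliberate protocol properties (kept, not "fixed"): key derivation is one
unsalted, un-iterated SHA-256, so low-entropy passcodes are open to
dictionary attack; choose passcodes accordingly.
"""

from __future__ import annotations

import hmac
import json
import unicodedata
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Union

from .errors import (
    AuthenticationError,
    ConfigurationError,
    FormatError,
    PhicryptError,
    TamperError,
    ValidationError,
)
from .primitives import sha256_hex

__all__ = [
    "EncryptionKey",
    "KeyEnvelope",
    "EscrowBundle",
    "normalize_passcode",
    "derive_key",
    "verification_hash",
    "verify_passcode",
    "wrap_key",
    "unwrap_key",
    "escrow_export",
    "read_sidecar",
    "write_sidecar",
    "SIDECAR_FORMAT_VERSION",
]

SIDECAR_FORMAT_VERSION = 1

_HEX_ALPHABET = set("0123456789abcdef")


def _is_hex_digest(text: object) -> bool:
    return isinstance(text, str) and len(text) == 64 and set(text) <= _HEX_ALPHABET


@dataclass(frozen=True)
class EncryptionKey:
    """A 256-bit AES key with its canonical lowercase-hex spelling.

    ``key_hex`` is the authoritative form: it is what gets hashed into the
    verification hash and what gets wrapped in a key envelope.
    """

    key_hex: str

    def __post_init__(self) -> None:
        if not _is_hex_digest(self.key_hex):
            raise ValidationError("key_hex must be 64 lowercase hex characters")

    @property
    def key_bytes(self) -> bytes:
        return bytes.fromhex(self.key_hex)

    def __repr__(self) -> str:  # never leak key material via repr/logs
        return "EncryptionKey(<redacted>)"


@dataclass(frozen=True)
class KeyEnvelope:
    """Server-storable record of the two-tier scheme.

    ``wrapped_key`` is a field-cipher container holding the participant
    key's hex form encrypted under the site key.
    """

    participant_vh: str
    wrapped_key: str
    site_vh: str

    def __post_init__(self) -> None:
        for name in ("participant_vh", "site_vh"):
            if not _is_hex_digest(getattr(self, name)):
                raise ValidationError(f"{name} must be 64 lowercase hex characters")
        if not self.wrapped_key:
            raise ValidationError("wrapped_key must be non-empty")

    def to_dict(self) -> dict:
        return {
            "participant_vh": self.participant_vh,
            "wrapped_key": self.wrapped_key,
            "site_vh": self.site_vh,
            "format_version": SIDECAR_FORMAT_VERSION,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "KeyEnvelope":
        try:
            return cls(
                participant_vh=data["participant_vh"],
                wrapped_key=data["wrapped_key"],
                site_vh=data["site_vh"],
            )
        except KeyError as exc:
            raise FormatError(f"key envelope missing field {exc}") from exc


@dataclass(frozen=True)
class EscrowBundle:
    """Sealed-envelope deposit: passcode, derived key, verification hash.

    Handed to an escrow agent so a site that loses its passcode can recover
    access; the agent holds secrets but no database credentials.
    """

    passcode: str
    key_hex: str
    verification_hash: str
    created: str  # ISO-8601 UTC timestamp

    def check(self) -> bool:
        """True iff passcode → key → hash re-derivation is self-consistent."""
        key = derive_key(self.passcode)
        return key.key_hex == self.key_hex and verification_hash(key) == self.verification_hash

    def to_dict(self) -> dict:
        return {
            "passcode": self.passcode,
            "key_hex": self.key_hex,
            "verification_hash": self.verification_hash,
            "created": self.created,
            "format_version": SIDECAR_FORMAT_VERSION,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EscrowBundle":
        try:
            return cls(
                passcode=data["passcode"],
                key_hex=data["key_hex"],
                verification_hash=data["verification_hash"],
                created=data["created"],
            )
        except KeyError as exc:
            raise FormatError(f"escrow bundle missing field {exc}") from exc


def normalize_passcode(passcode: str) -> str:
    """NFC-normalize a passcode, rejecting empty or non-string input.

    Normalization keeps visually identical text entered on different
    platforms from silently deriving different keys.
    """
    if not isinstance(passcode, str):
        raise ValidationError("passcode must be text")
    if passcode == "":
        raise ValidationError("You did not enter an encryption passcode.")
    return unicodedata.normalize("NFC", passcode)


def derive_key(passcode: str) -> EncryptionKey:
    """Expand a passcode to a 256-bit key: SHA-256 of its UTF-8 octets."""
    return EncryptionKey(key_hex=sha256_hex(normalize_passcode(passcode).encode("utf-8")))


def verification_hash(key: EncryptionKey) -> str:
    """SHA-256 of the ASCII octets of the key's hex form (not raw bytes)."""
    return sha256_hex(key.key_hex.encode("ascii"))


def verify_passcode(passcode: str, expected: str) -> bool:
    """True iff *passcode* derives a key whose verification hash is *expected*.

    Comparison is constant-time. A missing expected hash is a configuration
    error, not a failed verification.
    """
    if not expected:
        raise ConfigurationError("There is no verification hash available.")
    actual = verification_hash(derive_key(passcode))
    return hmac.compare_digest(actual, expected)


def wrap_key(participant_passcode: str, site_passcode: str) -> KeyEnvelope:
    """Build the two-tier envelope for one participant.

    The participant *key* (its hex form, a fixed-length non-human secret) is
    what gets wrapped under the site key — not the passcode itself.
    """
    p_norm = normalize_passcode(participant_passcode)
    s_norm = normalize_passcode(site_passcode)
    if p_norm == s_norm:
        raise ValidationError(
            "participant and site passcodes are identical; the envelope would add nothing"
        )
    from .fieldcrypt import encrypt_field  # local import: fieldcrypt builds on this module

    p_key = derive_key(p_norm)
    s_key = derive_key(s_norm)
    return KeyEnvelope(
        participant_vh=verification_hash(p_key),
        wrapped_key=encrypt_field(p_key.key_hex, s_key),
        site_vh=verification_hash(s_key),
    )


def unwrap_key(envelope: KeyEnvelope, passcode: str, role: str) -> EncryptionKey:
    """Recover the participant data key via either tier.

    role="participant": verify against ``participant_vh``, derive directly.
    role="site": verify against ``site_vh``, decrypt ``wrapped_key``, check
    the recovered key against ``participant_vh`` (detects tampering).
    """
    if role not in ("participant", "site"):
        raise ValidationError(f"role must be 'participant' or 'site', got {role!r}")
    if role == "participant":
        if not verify_passcode(passcode, envelope.participant_vh):
            raise AuthenticationError(
                "passcode does not verify against the participant hash",
                which="participant",
            )
        return derive_key(passcode)

    if not verify_passcode(passcode, envelope.site_vh):
        raise AuthenticationError(
            "passcode does not verify against the site hash", which="site"
        )
    from .fieldcrypt import decrypt_field

    site_key = derive_key(passcode)
    try:
        recovered_hex = decrypt_field(envelope.wrapped_key, site_key)
    except PhicryptError as exc:  # any decode failure here is tampering
        raise TamperError(f"wrapped key failed to decrypt: {exc}") from exc
    if not _is_hex_digest(recovered_hex):
        raise TamperError("decrypted wrapped key is not a valid key encoding")
    key = EncryptionKey(key_hex=recovered_hex)
    if not hmac.compare_digest(verification_hash(key), envelope.participant_vh):
        raise TamperError(
            "recovered participant key does not match the participant verification hash"
        )
    return key


def escrow_export(passcode: str, *, created: str | None = None) -> EscrowBundle:
    """Assemble the escrow deposit for a passcode."""
    norm = normalize_passcode(passcode)
    key = derive_key(norm)
    return EscrowBundle(
        passcode=norm,
        key_hex=key.key_hex,
        verification_hash=verification_hash(key),
        created=created or datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


# --- sidecar file I/O -------------------------------------------------------

Sidecar = Union[KeyEnvelope, str]  # envelope, or a bare verification hash


def write_sidecar(sidecar: Sidecar, path: str | Path) -> None:
    """Write a key sidecar file (JSON): envelope or bare verification hash."""
    if isinstance(sidecar, KeyEnvelope):
        payload = sidecar.to_dict()
    elif _is_hex_digest(sidecar):
        payload = {"verification_hash": sidecar, "format_version": SIDECAR_FORMAT_VERSION}
    else:
        raise ValidationError("sidecar must be a KeyEnvelope or a verification hash")
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_sidecar(path: str | Path) -> Sidecar:
    """Read a sidecar file; returns a KeyEnvelope or a bare hash string."""
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError("sidecar must be a JSON object")
    if "wrapped_key" in data:
        return KeyEnvelope.from_dict(data)
    vh = data.get("verification_hash")
    if not _is_hex_digest(vh):
        raise FormatError("sidecar holds no valid verification hash")
    return vh


def write_escrow(bundle: EscrowBundle, path: str | Path) -> None:
    json_text = json.dumps(bundle.to_dict(), indent=2) + "\n"
    Path(path).write_text(json_text, encoding="utf-8")


def read_escrow(path: str | Path) -> EscrowBundle:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"escrow file is not valid JSON: {exc}") from exc
    return EscrowBundle.from_dict(data)
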