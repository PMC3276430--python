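"""Field-level encryption and the per-field encryption-status machine.

Cipher container format (this package's definition, format_version 1):

    Base64( nonce[12] || AES-256-CTR ciphertext )

with a fresh random nonce per encryption. An empty value encrypts to an
empty value — missingness is deliberately visible without the key, so a
curator can tell "no data" from "data withheld". Two further properties are
inherent to the scheme and documented rather than hidden: the container
length reveals the UTF-8 plaintext length (CTR is length-preserving), and
there is no per-field authentication tag — corruption or a wrong key is
caught by the verification-hash gate and by UTF-8 decode failure, not by a
MAC.

Records carry a status flag per field so that encryption and decryption are
idempotent: an ``encrypted`` field is never ciphered again, a ``decrypted``
field is never deciphered again. On a failed passcode check, protected
fields are *locked* (the analogue of disabling a form input) and their
ciphertext is left byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional

from .errors import (
    AuthenticationError,
    ConfigurationError,
    FormatError,
    IntegrityError,
    ValidationError,
)
from .keyring import EncryptionKey, derive_key, verify_passcode
from .primitives import NONCE_LEN, b64_decode, b64_encode, ctr_crypt

__all__ = [
    "STATUS_ENCRYPTED",
    "STATUS_DECRYPTED",
    "FieldValue",
    "Record",
    "encrypt_field",
    "decrypt_field",
    "encrypt_record",
    "decrypt_record",
    "decrypt_record_with_key",
]

STATUS_ENCRYPTED = "encrypted"
STATUS_DECRYPTED = "decrypted"

NonceFactory = Callable[[], bytes]


def encrypt_field(
    plaintext: str, key: EncryptionKey, nonce: Optional[bytes] = None
) -> str:
    """Encrypt one field value into a Base64 cipher container.

    The empty string maps to the empty string (no container is emitted for a
    missing value). *nonce* is for tests and key wrapping only; production
    callers leave it None and get a fresh random nonce per call.
    """
    if not isinstance(plaintext, str):
        raise ValidationError("plaintext must be text")
    if plaintext == "":
        return ""
    if nonce is None:
        nonce = os.urandom(NONCE_LEN)
    elif len(nonce) != NONCE_LEN:
        raise ValidationError(f"nonce must be {NONCE_LEN} octets")
    return b64_encode(nonce + ctr_crypt(key.key_bytes, nonce, plaintext.encode("utf-8")))


def decrypt_field(container: str, key: EncryptionKey) -> str:
    """Decrypt a cipher container back to text.

    The empty string maps to the empty string. Raises :class:`FormatError`
    for malformed containers and :class:`IntegrityError` when the decrypted
    octets are not valid UTF-8 — the symptom of a wrong key or corruption.
    """
    if not isinstance(container, str):
        raise ValidationError("container must be text")
    if container == "":
        return ""
    raw = b64_decode(container)  # FormatError on bad Base64
    if len(raw) < NONCE_LEN:
        raise FormatError(
            f"cipher container holds {len(raw)} octets, shorter than the {NONCE_LEN}-octet nonce"
        )
    nonce, ciphertext = raw[:NONCE_LEN], raw[NONCE_LEN:]
    plain = ctr_crypt(key.key_bytes, nonce, ciphertext)
    try:
        return plain.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise IntegrityError(
            "decrypted octets are not valid UTF-8 (wrong key or corrupted container)"
        ) from exc


@dataclass(frozen=True)
class FieldValue:
    """One record cell: content plus its encryption status.

    Unprotected fields pass through every operation untouched; their status
    flag is carried but never acted on.
    """

    name: str
    content: str
    status: str = STATUS_DECRYPTED
    protected: bool = False
    locked: bool = False

    def __post_init__(self) -> None:
        if self.status not in (STATUS_ENCRYPTED, STATUS_DECRYPTED):
            raise ValidationError(f"unknown encryption status {self.status!r}")


@dataclass(frozen=True)
class Record:
    """An ordered collection of uniquely named fields."""

    fields: tuple[FieldValue, ...]

    def __init__(self, fields: Iterable[FieldValue]):
        fields = tuple(fields)
        names = [f.name for f in fields]
        if len(set(names)) != len(names):
            raise ValidationError("field names must be unique within a record")
        object.__setattr__(self, "fields", fields)

    def __getitem__(self, name: str) -> FieldValue:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def __iter__(self):
        return iter(self.fields)

    def map_fields(self, fn: Callable[[FieldValue], FieldValue]) -> "Record":
        return Record(fn(f) for f in self.fields)


def encrypt_record(
    record: Record, key: EncryptionKey, nonce_factory: Optional[NonceFactory] = None
) -> Record:
    """Encrypt every protected, currently-decrypted field of *record*.

    Content is whitespace-trimmed before encryption (form-input semantics).
    Fields already encrypted are left bit-identical — applying this twice is
    the same as applying it once. *nonce_factory* lets tests inject fixed
    nonces; by default each field draws a fresh random nonce.
    """

    def step(f: FieldValue) -> FieldValue:
        if not f.protected or f.status != STATUS_DECRYPTED:
            return f
        trimmed = f.content.strip()
        nonce = nonce_factory() if nonce_factory is not None else None
        return replace(f, content=encrypt_field(trimmed, key, nonce), status=STATUS_ENCRYPTED)

    return record.map_fields(step)


def decrypt_record_with_key(record: Record, key: EncryptionKey) -> Record:
    """Decrypt protected, currently-encrypted fields with an already-verified key.

    Callers must have passed the key through the verification-hash gate; the
    public entry point :func:`decrypt_record` does this. Exposed separately
    for bulk decryption, where the gate runs once for the whole dataset.
    """

    def step(f: FieldValue) -> FieldValue:
        if not f.protected or f.status != STATUS_ENCRYPTED:
            return f
        return replace(f, content=decrypt_field(f.content, key), status=STATUS_DECRYPTED)

    return record.map_fields(step)


def _lock_protected(record: Record) -> Record:
    return record.map_fields(
        lambda f: replace(f, locked=True) if f.protected else f
    )


def decrypt_record(record: Record, passcode: str, expected: Optional[str]) -> Record:
    """Verify the passcode, then decrypt the record's protected fields.

    If the record has no encrypted protected fields, no passcode interaction
    happens at all. On verification failure an :class:`AuthenticationError`
    is raised carrying the record with protected fields locked; ciphertext is
    never modified on failure.
    """
    needs_key = any(f.protected and f.status == STATUS_ENCRYPTED for f in record)
    if not needs_key:
        return record
    if not expected:
        raise ConfigurationError("There is no verification hash available.")
    if not verify_passcode(passcode, expected):
        raise AuthenticationError(
            "The passcode you entered does not verify. Encrypted fields will be disabled.",
            which="participant",
            record=_lock_protected(record),
        )
    return decrypt_record_with_key(record, derive_key(passcode))
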