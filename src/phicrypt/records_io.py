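"""Datasets on disk: schema, CSV/JSON I/O, bulk crypto, server views, fixtures.

A *dataset* is an ordered set of records conforming to a schema that marks
each column protected or not, plus a *sidecar* (a bare verification hash,
or a two-tier key envelope) that travels in a separate file so the data
file alone is a valid server view. Bulk operations apply the field-level
status machine uniformly: bulk decryption verifies the passcode once, up
front, and either decrypts everything or touches nothing.

The *server view* is the projection a zero-knowledge data custodian may
hold: ciphertext, empty cells, unprotected values and verification hashes
only. Building one from a dataset that still contains protected plaintext
raises rather than leaks.

Logging: this module logs operation names and record counts through the
``phicrypt`` logger, never cell contents, passcodes or key material.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .errors import (
    AuthenticationError,
    ConfigurationError,
    FormatError,
    LeakPreventionError,
    SchemaError,
    ValidationError,
)
from .fieldcrypt import (
    STATUS_DECRYPTED,
    STATUS_ENCRYPTED,
    FieldValue,
    Record,
    decrypt_record_with_key,
    encrypt_record,
)
from .keyring import (
    EncryptionKey,
    KeyEnvelope,
    Sidecar,
    derive_key,
    unwrap_key,
    verification_hash,
    verify_passcode,
    wrap_key,
)

__all__ = [
    "Schema",
    "Dataset",
    "ServerView",
    "read_dataset",
    "write_dataset",
    "bulk_encrypt",
    "bulk_decrypt",
    "server_view",
    "generate_fixtures",
    "FIXTURE_SCHEMA",
]

log = logging.getLogger("phicrypt")


# --- schema -----------------------------------------------------------------

@dataclass(frozen=True)
class Schema:
    """Ordered column names with per-column protected flags."""

    columns: tuple[str, ...]
    protected: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise SchemaError("duplicate column names in schema")
        unknown = self.protected - set(self.columns)
        if unknown:
            raise SchemaError(f"protected flags for unknown columns: {sorted(unknown)}")

    def is_protected(self, name: str) -> bool:
        return name in self.protected

    @classmethod
    def from_fields(cls, fields: Sequence[dict]) -> "Schema":
        """Build from a list of ``{"name": ..., "protected": bool}`` entries."""
        try:
            columns = tuple(f["name"] for f in fields)
            protected = frozenset(f["name"] for f in fields if f.get("protected", False))
        except (TypeError, KeyError) as exc:
            raise SchemaError(f"malformed schema field list: {exc}") from exc
        return cls(columns=columns, protected=protected)

    @classmethod
    def from_file(cls, path: str | Path) -> "Schema":
        """Load a schema from YAML or JSON: ``{"fields": [{name, protected}...]}``."""
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = yaml.safe_load(text)  # YAML is a JSON superset
        except yaml.YAMLError as exc:
            raise SchemaError(f"schema file does not parse: {exc}") from exc
        if not isinstance(data, dict) or "fields" not in data:
            raise SchemaError("schema file must be a mapping with a 'fields' list")
        return cls.from_fields(data["fields"])

    def to_file(self, path: str | Path) -> None:
        payload = {
            "fields": [
                {"name": c, "protected": self.is_protected(c)} for c in self.columns
            ]
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


# --- dataset ----------------------------------------------------------------

@dataclass(frozen=True)
class Dataset:
    """Schema + records + optional key sidecar + free-text provenance."""

    schema: Schema
    records: tuple[Record, ...]
    sidecar: Optional[Sidecar] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        for i, rec in enumerate(self.records):
            names = tuple(f.name for f in rec)
            if names != self.schema.columns:
                raise SchemaError(
                    f"record {i} columns {names} do not match schema {self.schema.columns}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def expected_hash(self) -> Optional[str]:
        """The verification hash guarding this dataset, if a sidecar is present."""
        if isinstance(self.sidecar, KeyEnvelope):
            return self.sidecar.participant_vh
        return self.sidecar

    def rows(self) -> list[dict[str, str]]:
        return [{f.name: f.content for f in rec} for rec in self.records]


def _record_from_row(
    row: dict[str, str], schema: Schema, status: str
) -> Record:
    return Record(
        FieldValue(
            name=c,
            content=row.get(c, ""),
            status=status,
            protected=schema.is_protected(c),
        )
        for c in schema.columns
    )


def dataset_from_rows(
    rows: Iterable[dict[str, str]],
    schema: Schema,
    status: str = STATUS_DECRYPTED,
    sidecar: Optional[Sidecar] = None,
    provenance: str = "",
) -> Dataset:
    """Assemble a Dataset from plain dict rows (all cells text)."""
    return Dataset(
        schema=schema,
        records=tuple(_record_from_row(r, schema, status) for r in rows),
        sidecar=sidecar,
        provenance=provenance,
    )


# --- readers / writers ------------------------------------------------------

def _infer_format(path: str | Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValidationError(f"unknown dataset format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValidationError(f"cannot infer dataset format from {path}")


def _check_columns(found: Sequence[str], schema: Schema, where: str) -> None:
    if tuple(found) != schema.columns:
        missing = [c for c in schema.columns if c not in found]
        extra = [c for c in found if c not in schema.columns]
        raise SchemaError(
            f"{where}: columns do not match schema"
            f" (missing {missing or 'none'}, unexpected {extra or 'none'})"
        )


def read_dataset(
    path: str | Path,
    schema: Schema,
    fmt: Optional[str] = None,
    status: str = STATUS_ENCRYPTED,
) -> Dataset:
    """Read a CSV or JSON dataset file against *schema*.

    Protected fields are assumed to arrive encrypted (the on-server state);
    pass ``status="decrypted"`` when reading a plaintext export. Empty cells
    and missing JSON keys become empty strings.
    """
    fmt = _infer_format(path, fmt)
    text = Path(path).read_text(encoding="utf-8")
    rows: list[dict[str, str]] = []
    if fmt == "csv":
        reader = csv.reader(io.StringIO(text))
        try:
            header = next(reader, None)
            if header is None:
                raise FormatError(f"{path}: empty CSV, header row required")
            _check_columns(header, schema, str(path))
            for lineno, cells in enumerate(reader, start=2):
                if len(cells) != len(header):
                    raise FormatError(
                        f"{path}: line {lineno}: {len(cells)} cells, expected {len(header)}"
                    )
                rows.append(dict(zip(header, cells)))
        except csv.Error as exc:
            raise FormatError(f"{path}: line {reader.line_num}: {exc}") from exc
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        if not isinstance(data, list):
            raise FormatError(f"{path}: JSON dataset must be an array of records")
        for i, item in enumerate(data):
            if not isinstance(item, dict):
                raise FormatError(f"{path}: record {i} is not an object")
            extra = set(item) - set(schema.columns)
            if extra:
                raise SchemaError(f"{path}: record {i} has unknown columns {sorted(extra)}")
            rows.append({c: _coerce_cell(item.get(c, ""), f"record {i}", c) for c in schema.columns})
    log.info("read_dataset: %d records from %s (%s)", len(rows), path, fmt)
    return dataset_from_rows(rows, schema, status=status)


def _coerce_cell(value: object, where: str, column: str) -> str:
    if value is None:
        return ""
    if not isinstance(value, str):
        raise FormatError(f"{where}, column {column!r}: cell must be text or null")
    return value


def write_dataset(dataset: Dataset, path: str | Path, fmt: Optional[str] = None) -> None:
    """Write *dataset* as CSV (RFC 4180-style, UTF-8, header row) or JSON."""
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(dataset.schema.columns)
        for rec in dataset.records:
            writer.writerow([f.content for f in rec])
        Path(path).write_text(buf.getvalue(), encoding="utf-8")
    else:
        Path(path).write_text(
            json.dumps(dataset.rows(), ensure_ascii=False, indent=1) + "\n",
            encoding="utf-8",
        )
    log.info("write_dataset: %d records to %s (%s)", len(dataset), path, fmt)


# --- bulk crypto ------------------------------------------------------------

def bulk_encrypt(
    dataset: Dataset,
    passcode: str,
    site_passcode: Optional[str] = None,
    nonce_factory=None,
) -> Dataset:
    """Encrypt every record and attach the sidecar.

    With only *passcode*, the sidecar is that passcode's bare verification
    hash. With *site_passcode* as well, the sidecar is a two-tier key
    envelope: data encrypted under the participant passcode's key, that key
    wrapped under the site key.
    """
    key = derive_key(passcode)
    sidecar: Sidecar
    if site_passcode is not None:
        sidecar = wrap_key(passcode, site_passcode)
    else:
        sidecar = verification_hash(key)
    records = tuple(encrypt_record(r, key, nonce_factory) for r in dataset.records)
    log.info("bulk_encrypt: %d records", len(records))
    return replace(dataset, records=records, sidecar=sidecar)


def bulk_decrypt(dataset: Dataset, passcode: str, role: str = "participant") -> Dataset:
    """Verify once, then decrypt every record — all-or-nothing.

    *role* selects the unlock path when the sidecar is a key envelope:
    participants verify and derive directly, site staff unwrap the
    participant key with the site passcode. Verification failure aborts
    before any record is touched; the input dataset is never mutated.
    """
    if dataset.sidecar is None:
        raise ConfigurationError("There is no verification hash available.")
    if isinstance(dataset.sidecar, KeyEnvelope):
        key = unwrap_key(dataset.sidecar, passcode, role)  # raises on failure
    else:
        if role != "participant":
            raise ConfigurationError(
                "dataset sidecar is a bare verification hash; only the participant path exists"
            )
        if not verify_passcode(passcode, dataset.sidecar):
            raise AuthenticationError(
                "The passcode you entered does not verify.", which="participant"
            )
        key = derive_key(passcode)
    records = tuple(decrypt_record_with_key(r, key) for r in dataset.records)
    log.info("bulk_decrypt: %d records", len(records))
    return replace(dataset, records=records)


# --- server view ------------------------------------------------------------

@dataclass(frozen=True)
class ServerView:
    """What the data custodian may hold: ciphertext and hashes only."""

    schema: Schema
    records: tuple[Record, ...]
    sidecar: Optional[Sidecar] = None

    def serialize(self, fmt: str = "json") -> str:
        """Render the view as it would be stored or transmitted."""
        ds = Dataset(schema=self.schema, records=self.records, sidecar=self.sidecar)
        if fmt == "csv":
            buf = io.StringIO()
            writer = csv.writer(buf, lineterminator="\n")
            writer.writerow(ds.schema.columns)
            for rec in ds.records:
                writer.writerow([f.content for f in rec])
            body = buf.getvalue()
        elif fmt == "json":
            body = json.dumps(ds.rows(), ensure_ascii=False)
        else:
            raise ValidationError(f"unknown serialization format {fmt!r}")
        sidecar_text = ""
        if isinstance(self.sidecar, KeyEnvelope):
            sidecar_text = json.dumps(self.sidecar.to_dict())
        elif isinstance(self.sidecar, str):
            sidecar_text = json.dumps({"verification_hash": self.sidecar})
        return body + ("\n" + sidecar_text if sidecar_text else "")


def server_view(dataset: Dataset) -> ServerView:
    """Project a dataset to its server-storable form.

    Refuses (raises :class:`LeakPreventionError`) if any protected field is
    still decrypted — the one state that must never reach the server.
    """
    for i, rec in enumerate(dataset.records):
        for f in rec:
            if f.protected and f.status != STATUS_ENCRYPTED:
                raise LeakPreventionError(
                    f"record {i}, field {f.name!r}: protected field is not encrypted"
                )
    return ServerView(schema=dataset.schema, records=dataset.records, sidecar=dataset.sidecar)


# --- synthetic fixtures -----------------------------------------------------

FIXTURE_SCHEMA = Schema(
    columns=(
        "study_id",
        "site",
        "first_name",
        "last_name",
        "street_address",
        "phone",
        "email",
        "birth_date",
        "enrollment_offset",
        "last_contact_offset",
    ),
    protected=frozenset(
        {"first_name", "last_name", "street_address", "phone", "email", "birth_date"}
    ),
)

_FIRST_NAMES = (
    "Alice", "Brian", "Carla", "Derek", "Elena", "Felix", "Grace", "Hugo",
    "Irene", "James", "Karen", "Louis", "Maria", "Nathan", "Olivia", "Peter",
    "Quinn", "Rosa", "Samuel", "Teresa", "Ulysses", "Vera", "Walter", "Ximena",
    "Yusuf", "Zoe", "Anders", "Beatriz", "Chinwe", "Dmitri", "Esperanza", "François",
)
_LAST_NAMES = (
    "Abbott", "Barnes", "Castillo", "Delgado", "Emerson", "Fitzgerald", "Gustafsson",
    "Hernandez", "Ivanova", "Jackson", "Kowalski", "Lindqvist", "Martinez", "Nakamura",
    "O'Connell", "Petrov", "Quintero", "Rossi", "Svensson", "Takahashi", "Underwood",
    "Vasquez", "Whitaker", "Xu", "Yamamoto", "Zielinski", "Müller", "Nuñez",
)
_STREETS = (
    "Maple St", "Oak Ave", "Cedar Ln", "Birch Rd", "Elm Dr", "Willow Way",
    "Chestnut Blvd", "Spruce Ct", "Aspen Ter", "Staniford St", "Harbor View Rd",
    "Sunset Pkwy", "Riverbend Ave", "Hillcrest Dr",
)
_SITES = tuple(f"SITE{i:02d}" for i in range(1, 16))

EMPTY_CELL_RATE = 0.05  # fraction of protected cells left empty


def generate_fixtures(n: int, seed: int) -> Dataset:
    """Deterministic synthetic contact records (no real persons).

    Stands in for registry contact data, which is never published: names,
    addresses, phones and emails drawn from fixed lists, a protected birth
    date serving as the per-subject base date, and unprotected day-offset
    columns for enrollment and last contact. About 5% of protected cells
    are empty, to exercise the missing-value contract.
    """
    import random

    if n < 1:
        raise ValidationError("fixture count must be >= 1")
    rng = random.Random(seed)
    rows = []
    for i in range(n):
        first = rng.choice(_FIRST_NAMES)
        last = rng.choice(_LAST_NAMES)
        birth = _random_date(rng, 1930, 1995)
        row = {
            "study_id": f"CGN-{seed % 1000:03d}-{i:06d}",
            "site": rng.choice(_SITES),
            "first_name": first,
            "last_name": last,
            "street_address": f"{rng.randrange(1, 2000)} {rng.choice(_STREETS)}",
            "phone": f"({rng.randrange(200, 1000)}) {rng.randrange(200, 1000)}-{rng.randrange(0, 10000):04d}",
            "email": f"{first.lower()}.{last.lower().replace(' ', '').replace(chr(39), '')}@example.org",
            "birth_date": birth.isoformat(),
            "enrollment_offset": str(rng.randrange(15000, 28000)),
            "last_contact_offset": str(rng.randrange(28000, 34000)),
        }
        for col in FIXTURE_SCHEMA.columns:  # fixed order: frozenset order is not reproducible
            if FIXTURE_SCHEMA.is_protected(col) and rng.random() < EMPTY_CELL_RATE:
                row[col] = ""
        rows.append(row)
    return dataset_from_rows(
        rows,
        FIXTURE_SCHEMA,
        status=STATUS_DECRYPTED,
        provenance=f"synthetic fixtures, n={n}, seed={seed}",
    )


def _random_date(rng, year_lo: int, year_hi: int):
    import datetime as dt

    start = dt.date(year_lo, 1, 1).toordinal()
    end = dt.date(year_hi, 12, 31).toordinal()
    return dt.date.fromordinal(rng.randrange(start, end + 1))
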