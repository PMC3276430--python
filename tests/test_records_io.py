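"""Dataset I/O, bulk crypto, server views and the fixture generator."""

import dataclasses
import json
import logging

import pytest

import phicrypt as pc
from phicrypt.records_io import EMPTY_CELL_RATE, FIXTURE_SCHEMA, dataset_from_rows

SCHEMA = pc.Schema(columns=("name", "phone", "site"), protected=frozenset({"name", "phone"}))

ROWS = [
    {"name": "Ada Lovelace", "phone": "(617) 555-0100", "site": "SITE01"},
    {"name": "Grace Hopper", "phone": "", "site": "SITE02"},
    {"name": "πλάτων — 𝄞", "phone": "555,with\"quotes\"", "site": ""},
]


def plain_dataset():
    return dataset_from_rows(ROWS, SCHEMA, status=pc.STATUS_DECRYPTED)


class TestSchema:
    def test_yaml_file_round_trip(self, tmp_path):
        path = tmp_path / "schema.yaml"
        SCHEMA.to_file(path)
        assert pc.Schema.from_file(path) == SCHEMA

    def test_json_schema_also_parses(self, tmp_path):
        path = tmp_path / "schema.json"
        path.write_text(json.dumps({"fields": [{"name": "a", "protected": True}]}))
        schema = pc.Schema.from_file(path)
        assert schema.columns == ("a",) and schema.is_protected("a")

    def test_duplicate_columns_rejected(self):
        with pytest.raises(pc.SchemaError):
            pc.Schema(columns=("a", "a"), protected=frozenset())


class TestDatasetIO:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_lossless_round_trip(self, tmp_path, fmt):
        ds = plain_dataset()
        path = tmp_path / f"data.{fmt}"
        pc.write_dataset(ds, path)
        back = pc.read_dataset(path, SCHEMA, status=pc.STATUS_DECRYPTED)
        assert back.rows() == ds.rows()

    def test_csv_and_json_read_identically(self, tmp_path):
        ds = plain_dataset()
        pc.write_dataset(ds, tmp_path / "d.csv")
        pc.write_dataset(ds, tmp_path / "d.json")
        csv_ds = pc.read_dataset(tmp_path / "d.csv", SCHEMA)
        json_ds = pc.read_dataset(tmp_path / "d.json", SCHEMA)
        assert csv_ds.rows() == json_ds.rows()

    def test_empty_cells_become_empty_field_values(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("name,phone,site\n,,\n")  # one row of empty cells
        ds = pc.read_dataset(path, SCHEMA)
        assert all(f.content == "" for f in ds.records[0])

    def test_column_mismatch_names_the_columns(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("name,telephone,site\nx,y,z\n")
        with pytest.raises(pc.SchemaError, match="telephone"):
            pc.read_dataset(path, SCHEMA)

    def test_malformed_csv_reports_line(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("name,phone,site\nok,ok,ok\nonly,two\n")
        with pytest.raises(pc.FormatError, match="line 3"):
            pc.read_dataset(path, SCHEMA)

    def test_malformed_json_reports_line(self, tmp_path):
        path = tmp_path / "d.json"
        path.write_text('[\n{"name": "x", "phone": "y", "site": "z"},\nnonsense\n]')
        with pytest.raises(pc.FormatError, match="line"):
            pc.read_dataset(path, SCHEMA)


class TestBulkCrypto:
    def test_bulk_round_trip(self):
        ds = plain_dataset()
        enc = pc.bulk_encrypt(ds, "sitepass")
        dec = pc.bulk_decrypt(enc, "sitepass")
        # whitespace-trim on encryption is the only permitted difference
        assert dec.rows() == [
            {k: v.strip() if SCHEMA.is_protected(k) else v for k, v in row.items()}
            for row in ds.rows()
        ]

    def test_sidecar_emitted_on_encrypt(self):
        enc = pc.bulk_encrypt(plain_dataset(), "sitepass")
        assert enc.sidecar == pc.verification_hash(pc.derive_key("sitepass"))

    def test_envelope_sidecar_with_site_passcode(self):
        enc = pc.bulk_encrypt(plain_dataset(), "partpass", site_passcode="sitepass")
        assert isinstance(enc.sidecar, pc.KeyEnvelope)
        assert pc.bulk_decrypt(enc, "partpass").rows() == pc.bulk_decrypt(
            enc, "sitepass", role="site"
        ).rows()

    def test_wrong_passcode_aborts_without_touching_ciphertext(self):
        enc = pc.bulk_encrypt(plain_dataset(), "sitepass")
        before = enc.rows()
        with pytest.raises(pc.AuthenticationError):
            pc.bulk_decrypt(enc, "wrong")
        assert enc.rows() == before

    def test_decrypt_without_sidecar_is_configuration_error(self):
        enc = pc.bulk_encrypt(plain_dataset(), "sitepass")
        stripped = dataclasses.replace(enc, sidecar=None)
        with pytest.raises(pc.ConfigurationError):
            pc.bulk_decrypt(stripped, "sitepass")


class TestServerView:
    def test_encrypted_dataset_passes(self):
        enc = pc.bulk_encrypt(plain_dataset(), "sitepass")
        view = pc.server_view(enc)
        assert view.serialize("json")

    def test_decrypted_protected_field_refused(self):
        with pytest.raises(pc.LeakPreventionError):
            pc.server_view(plain_dataset())

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_no_plaintext_substring_in_serialized_view(self, fmt):
        ds = plain_dataset()
        secrets = [
            f.content.strip()
            for rec in ds.records
            for f in rec
            if f.protected and len(f.content.strip()) >= 4
        ]
        view = pc.server_view(pc.bulk_encrypt(ds, "sitepass")).serialize(fmt)
        for secret in secrets:
            assert secret not in view


class TestFixtures:
    def test_same_seed_same_dataset(self):
        assert pc.generate_fixtures(100, 11) == pc.generate_fixtures(100, 11)

    def test_different_seed_differs(self):
        assert pc.generate_fixtures(100, 11) != pc.generate_fixtures(100, 12)

    def test_count(self):
        assert len(pc.generate_fixtures(250, 5)) == 250

    def test_empty_cell_rate_within_binomial_bounds(self):
        n = 4000
        ds = pc.generate_fixtures(n, 9)
        n_protected = len(FIXTURE_SCHEMA.protected)
        trials = n * n_protected
        empties = sum(
            1 for rec in ds.records for f in rec if f.protected and f.content == ""
        )
        mean = trials * EMPTY_CELL_RATE
        sigma = (trials * EMPTY_CELL_RATE * (1 - EMPTY_CELL_RATE)) ** 0.5
        assert abs(empties - mean) <= 3 * sigma

    def test_records_are_decrypted_plaintext(self):
        ds = pc.generate_fixtures(5, 1)
        assert all(f.status == pc.STATUS_DECRYPTED for rec in ds.records for f in rec)


class TestEndToEndPipeline:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_generate_encrypt_write_read_view_decrypt(self, tmp_path, seed, fmt):
        ds = pc.generate_fixtures(40, seed)
        enc = pc.bulk_encrypt(ds, f"pass-{seed}")
        path = tmp_path / f"data.{fmt}"
        pc.write_dataset(enc, path)
        back = pc.read_dataset(path, ds.schema)
        back = dataclasses.replace(back, sidecar=enc.sidecar)
        pc.server_view(back)  # must pass the leak gate
        dec = pc.bulk_decrypt(back, f"pass-{seed}")
        assert dec.rows() == ds.rows()  # fixture content is pre-trimmed

    def test_no_secret_in_logs(self, caplog, tmp_path):
        """The phicrypt logger never emits passcodes, keys, or cell contents."""
        with caplog.at_level(logging.DEBUG, logger="phicrypt"):
            ds = pc.generate_fixtures(20, 4)
            enc = pc.bulk_encrypt(ds, "secret-passcode")
            pc.write_dataset(enc, tmp_path / "x.csv")
            back = pc.read_dataset(tmp_path / "x.csv", ds.schema)
            back = dataclasses.replace(back, sidecar=enc.sidecar)
            pc.bulk_decrypt(back, "secret-passcode")
        log_text = "\n".join(r.getMessage() for r in caplog.records)
        assert "secret-passcode" not in log_text
        key = pc.derive_key("secret-passcode")
        assert key.key_hex not in log_text
        for rec in ds.records:
            for f in rec:
                if f.protected and len(f.content) >= 4:
                    assert f.content not in log_text
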