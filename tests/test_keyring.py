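"""Key derivation, verification hashing, envelopes, escrow, sidecar files."""

import dataclasses
import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

import phicrypt as pc
from phicrypt.primitives import sha256_hex

PRINTED_VH = "a983169676c9fdcc852f29c013aef5f6faac345dfff472548bf93a543618d5ed"

passcodes = st.text(min_size=1, max_size=40).filter(lambda s: s.strip() != "" or s != "")


class TestDeriveKey:
    def test_worked_example(self):
        assert pc.verification_hash(pc.derive_key("passcode")) == PRINTED_VH

    def test_deterministic(self):
        assert pc.derive_key("alpha") == pc.derive_key("alpha")

    def test_empty_passcode_rejected(self):
        with pytest.raises(pc.ValidationError):
            pc.derive_key("")

    def test_nfc_normalization_unifies_composed_and_decomposed(self):
        composed = "café"       # é as one code point
        decomposed = "café"    # e + combining acute
        assert pc.derive_key(composed) == pc.derive_key(decomposed)

    def test_key_bytes_match_hex(self):
        key = pc.derive_key("alpha")
        assert key.key_bytes.hex() == key.key_hex

    def test_repr_redacts_key_material(self):
        key = pc.derive_key("alpha")
        assert key.key_hex not in repr(key)


class TestVerificationHash:
    def test_hashes_hex_string_not_raw_bytes(self):
        # the convention that makes the printed value reproducible
        key = pc.derive_key("passcode")
        assert pc.verification_hash(key) == sha256_hex(key.key_hex.encode("ascii"))
        assert sha256_hex(key.key_bytes) != PRINTED_VH

    @given(passcodes)
    def test_output_is_hex_digest(self, passcode):
        vh = pc.verification_hash(pc.derive_key(passcode))
        assert len(vh) == 64 and set(vh) <= set("0123456789abcdef")


class TestVerifyPasscode:
    def test_printed_pair_verifies(self):
        assert pc.verify_passcode("passcode", PRINTED_VH)

    def test_case_variant_fails(self):
        assert not pc.verify_passcode("Passcode", PRINTED_VH)

    @given(passcodes)
    def test_own_hash_always_verifies(self, passcode):
        vh = pc.verification_hash(pc.derive_key(passcode))
        assert pc.verify_passcode(passcode, vh)

    def test_random_wrong_passcodes_never_verify(self, rng):
        for _ in range(200):
            wrong = "pw-" + rng.randbytes(8).hex()
            assert not pc.verify_passcode(wrong, PRINTED_VH)

    def test_missing_hash_is_configuration_error(self):
        with pytest.raises(pc.ConfigurationError):
            pc.verify_passcode("passcode", "")


class TestEnvelope:
    def test_both_paths_yield_identical_key(self):
        env = pc.wrap_key("alpha", "beta")
        k_part = pc.unwrap_key(env, "alpha", "participant")
        k_site = pc.unwrap_key(env, "beta", "site")
        assert k_part == k_site == pc.derive_key("alpha")

    def test_many_random_pairs_agree(self, rng):
        for _ in range(50):
            p, s = "p" + rng.randbytes(6).hex(), "s" + rng.randbytes(6).hex()
            env = pc.wrap_key(p, s)
            assert pc.unwrap_key(env, p, "participant") == pc.unwrap_key(env, s, "site")

    def test_envelopes_differ_with_site_passcode(self):
        e1, e2 = pc.wrap_key("alpha", "beta"), pc.wrap_key("alpha", "gamma")
        assert e1.wrapped_key != e2.wrapped_key and e1.site_vh != e2.site_vh
        assert e1.participant_vh == e2.participant_vh

    def test_wrapped_key_is_valid_base64_container(self):
        from phicrypt.primitives import b64_decode

        env = pc.wrap_key("alpha", "beta")
        assert len(b64_decode(env.wrapped_key)) == 12 + 64  # nonce + key_hex octets

    def test_identical_passcodes_rejected(self):
        with pytest.raises(pc.ValidationError):
            pc.wrap_key("same", "same")

    def test_wrong_passcodes_name_the_failing_hash(self):
        env = pc.wrap_key("alpha", "beta")
        with pytest.raises(pc.AuthenticationError) as exc_info:
            pc.unwrap_key(env, "beta", "participant")
        assert exc_info.value.which == "participant"
        with pytest.raises(pc.AuthenticationError) as exc_info:
            pc.unwrap_key(env, "alpha", "site")
        assert exc_info.value.which == "site"

    def test_single_character_tampering_detected(self):
        env = pc.wrap_key("alpha", "beta")
        for i in range(0, len(env.wrapped_key) - 2, 7):
            flipped = "A" if env.wrapped_key[i] != "A" else "B"
            mutated = env.wrapped_key[:i] + flipped + env.wrapped_key[i + 1 :]
            bad = dataclasses.replace(env, wrapped_key=mutated)
            with pytest.raises((pc.TamperError, pc.FormatError)):
                pc.unwrap_key(bad, "beta", "site")

    def test_server_visible_strings_do_not_act_as_passcodes(self):
        """Operational zero-knowledge check: nothing the server stores works
        as a passcode for the data it guards."""
        env = pc.wrap_key("alpha", "beta")
        for stored in (env.participant_vh, env.site_vh, env.wrapped_key):
            assert not pc.verify_passcode(stored, env.participant_vh)
            assert not pc.verify_passcode(stored, env.site_vh)


class TestEscrow:
    def test_worked_example_hash(self):
        assert pc.escrow_export("passcode").verification_hash == PRINTED_VH

    @given(passcodes)
    def test_internally_consistent(self, passcode):
        assert pc.escrow_export(passcode).check()

    def test_file_round_trip(self, tmp_path):
        from phicrypt.keyring import read_escrow, write_escrow

        bundle = pc.escrow_export("alpha")
        path = tmp_path / "escrow.json"
        write_escrow(bundle, path)
        assert read_escrow(path) == bundle


class TestSidecarIO:
    def test_envelope_round_trip_and_field_names(self, tmp_path):
        env = pc.wrap_key("alpha", "beta")
        path = tmp_path / "sidecar.json"
        pc.write_sidecar(env, path)
        raw = json.loads(path.read_text())
        assert set(raw) == {"participant_vh", "wrapped_key", "site_vh", "format_version"}
        assert raw["format_version"] == 1
        assert pc.read_sidecar(path) == env

    def test_bare_hash_round_trip(self, tmp_path):
        vh = pc.verification_hash(pc.derive_key("alpha"))
        path = tmp_path / "sidecar.json"
        pc.write_sidecar(vh, path)
        assert pc.read_sidecar(path) == vh

    def test_malformed_sidecar_rejected(self, tmp_path):
        path = tmp_path / "sidecar.json"
        path.write_text("not json at all")
        with pytest.raises(pc.FormatError):
            pc.read_sidecar(path)
        path.write_text(json.dumps({"verification_hash": "tooshort"}))
        with pytest.raises(pc.FormatError):
            pc.read_sidecar(path)
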