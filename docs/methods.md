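# Methods

## Protocol

phicrypt implements a client-side encryption protocol for tabular records
in which a server acts as a zero-knowledge custodian of protected fields.

**Key derivation.** A passcode is NFC-normalized, UTF-8 encoded, and hashed
once with SHA-256; the 256-bit digest is the AES key. Its canonical form is
the 64-character lowercase hex string, because every downstream construct
(verification hash, key wrapping) operates on that string. Normalization is
a deliberate addition: composed and decomposed spellings of the same
visible text must not derive different keys across platforms. Derivation is
intentionally *not* salted or iterated — the protocol stores a
deterministic verification hash, and hardening derivation would change the
protocol rather than strengthen this implementation. The consequence, a
dictionary-attack surface proportional to passcode entropy, is documented
rather than silently "fixed".

**Verification hash.** `V = SHA-256(ASCII(hex(K)))`. The hash is computed
over the hex *string* of the key, not its raw bytes; the two differ, and
only the string convention is interoperable with the protocol's published
worked example. Hash comparisons use constant-time equality — a
no-protocol-change hardening.

**Field containers.** `Base64(nonce[12] ‖ CTR(K, nonce, UTF-8(text)))`,
fresh random nonce per encryption (`os.urandom`). Properties that are part
of the contract, not leaks to be patched later:

- empty ↔ empty: a missing value is missing in ciphertext too;
- container length = 12 + UTF-8 length: CTR is length-preserving, so field
  length is disclosed;
- no per-field MAC: wrong-key decryption is caught by the verification gate
  and, failing that, by UTF-8 decode failure. A wrong key that happens to
  yield valid UTF-8 is not detected at the field level.

**Status machine.** Every field carries `encrypted | decrypted`. Encryption
touches only protected+decrypted fields (after whitespace-trimming, which
applies on encryption only); decryption only protected+encrypted ones.
This makes both operations idempotent and prevents the classic
double-encryption corruption. On a failed passcode check the record is
returned with protected fields `locked` — the library analogue of
disabling form inputs — and ciphertext bit-identical.

**Two-tier envelope.** `wrap_key` encrypts the participant key's *hex
form* (not the passcode) under the site key, using the ordinary field
container format. Wrapping the key rather than the passcode gives a
fixed-length payload and avoids persisting a human-chosen secret even in
encrypted form; both choices were open, either would interoperate with
nothing else, and this one leaks less. `unwrap_key` on the site path
verifies the site passcode, decrypts, checks the result is a 64-char hex
digest, and finally checks it hashes to the stored participant verification
hash — so any single-character tampering of the stored `wrapped_key` is
detected (the Base64 decoder also rejects non-canonical trailing pad bits,
closing the one mutation class a lenient decoder would silently accept).

**Date shifting.** Dates are proleptic-Gregorian calendar dates (never
datetimes — these are rejected, since silently dropping a time component
invites off-by-one-day bugs around midnight). Offsets are exact signed
whole days. The base date is serialized as ISO-8601 text before
encryption, which makes parse-after-decrypt a cheap wrong-key detector;
the base may be any date, real or arbitrary, and decoding is invariant to
the choice. Offsets-only views preserve all pairwise intervals by
linearity.

**Bulk operations.** Bulk decryption verifies the passcode once, up front,
against the dataset sidecar and is all-or-nothing; per-record verification
would re-derive the same key ~n times and allow partial failure states
that have no meaning under a single dataset key. The sidecar (bare
verification hash, or envelope) travels in its own JSON file so the data
file alone is a valid server view. The `server_view` projection enforces,
rather than assumes, the no-plaintext invariant: it refuses any dataset
with a protected field still decrypted.

## Primitives

SHA-256 (FIPS 180-2), AES-256 (FIPS 197) with CTR mode (SP 800-38A), and
Base64 (RFC 4648) are implemented in-package: the encryption path is the
artifact's core and is meant to be auditable end-to-end, with no trust
placed in an undocumented wire format. Design points:

- The AES S-box and T-tables are *generated* from the GF(2⁸) arithmetic
  the standard defines, not transcribed — a transcription error would be
  caught nowhere, a generation error everywhere.
- The cipher is expressed over numpy `uint32` column arrays, so a CTR
  keystream of N blocks is one vectorized pass; single-block operations
  reuse the same core at N = 1. Key schedules are cached per key.
- Counter-block layout is fixed and documented: 12-octet nonce ‖ 32-bit
  big-endian counter from 0 (messages < 2³² blocks per nonce). This
  matches OpenSSL's `aes-256-ctr` with a zero 4-octet IV tail, which is
  what the cross-validation tests exploit.
- Base64 is strict on decode: standard alphabet, mandatory padding, and
  non-zero trailing pad bits rejected (canonical form), so distinct texts
  never decode to identical bytes.
- These are not constant-time, side-channel-hardened implementations; they
  target correctness and auditability on trusted client hardware.

Validation is dual-route throughout: published standard vectors (FIPS
180-2, FIPS 197 Appendix C.3, RFC 4648 §10) are frozen in the tests, and
the suite cross-checks random inputs against independent platform
references — `hashlib` for SHA-256, stdlib `base64`, and OpenSSL's
libcrypto (via ctypes) for AES-ECB and AES-CTR. The frozen field-container
regression value (`"A"` under the worked-example key with a zero nonce →
`AAAAAAAAAAAAAAAAtg==`) was computed with the platform oracle, not with
the code it checks.

## Synthetic fixtures

`generate_fixtures(n, seed)` emulates a registry contact table: per-record
name, street address, phone and email (protected), a protected birth date
that doubles as a date-shifting base, unprotected site/study-id columns,
and unprotected integer day-offset columns. Roughly 5% of protected cells
are empty (independent Bernoulli per cell) to exercise the missing-value
contract. Values are drawn deterministically (`random.Random(seed)`) from
fixed name/street lists — no real persons, no external data.

What the fixtures do *not* emulate: realistic name/address distributions,
free-text fields with newlines or exotic whitespace (covered instead by
property tests over full-range Unicode), correlated missingness, or
datasets large enough to stress memory. Passing tests therefore demonstrate
protocol correctness and format fidelity, not performance at registry scale
or robustness to adversarial real-world CSV dialects beyond RFC 4180
quoting.

## Problem sizes and numerical choices

The test and acceptance workloads are sized to what the guarantees need:
1000 random inputs per primitive against the platform references, 10,000
full-range Unicode strings (lengths 0–500) for round-trip identity, 1,000
wrong passcodes for the gate, 200 passcode pairs plus exhaustive
per-character tampering of five envelopes, 1,000 random date sets, and
three 1,000-record fixture datasets for the server-view substring scan.
Randomness in tests is seeded; hypothesis runs derandomized.

Degenerate inputs are pinned by tests: empty strings and empty datasets
round-trip; records with no protected fields require no passcode; a
dataset without a sidecar cannot be bulk-decrypted (configuration error,
not authentication failure); duplicate column names are rejected at
construction.

## Known limitations

- Verification gate, not authenticated encryption: field-level integrity
  against an adversarial server is out of scope (the threat model is a
  *curious* server, not a malicious one).
- Field length and missingness are visible by design.
- Single SHA-256 derivation: passcode entropy is the security floor.
- One key per dataset; rotation means re-encryption.
- Authentication, authorization, audit logging and transport security are
  the enclosing system's job.
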