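# phicrypt

Client-side field-level encryption for protected health information (PHI)
in tabular clinical-research data.

## The problem

Multi-site registries and trials often must centralize participant records
while guaranteeing that staff at the coordinating center — including
database administrators and developers — can never read the fields that
identify a person (names, addresses, phones, birth dates). Consent
agreements frequently permit central *storage* of contact data only if
access remains exclusively with the enrolling site. phicrypt implements the
zero-knowledge-custodian pattern that makes this possible: identifying
fields are encrypted and decrypted only on the client, and the server holds
nothing that can recover them.

## The scheme

- **Key derivation.** A human-memorable passcode *p* is expanded to an
  AES-256 key: `K = SHA-256(UTF-8(p))`, used via its lowercase-hex spelling
  `hex(K)`.
- **Verification hash.** The server stores `V = SHA-256(ASCII(hex(K)))` —
  a one-way digest of the key. Before decrypting, a client checks the typed
  passcode by hashing it twice and comparing with `V`. A mistyped passcode
  is caught *before* it can turn data into gibberish and re-save it; the
  server still learns nothing that decrypts.
- **Field encryption.** Each protected cell becomes
  `Base64(nonce‖AES-256-CTR(K, nonce, UTF-8(value)))` with a fresh 12-octet
  nonce; empty cells stay empty, so missingness is auditable without the
  key. A per-field status flag makes encryption and decryption idempotent
  (nothing is ever double-ciphered).
- **Two-tier envelope.** Data is encrypted under a per-participant key;
  that key is wrapped under a site-wide key. The server stores
  `{participant_vh, wrapped_key, site_vh}` — either passcode unlocks, the
  server still cannot.
- **Date shifting.** Each subject keeps one *encrypted* base date; all real
  dates are stored as signed whole-day offsets from it. Offsets alone
  preserve every between-date interval exactly and reveal no calendar
  position.
- **Escrow.** A site can deposit `{passcode, hex(K), V}` with a neutral
  agent who has no database access, so a lost passcode is recoverable.

SHA-256, AES-256 and Base64 are implemented in the package itself (FIPS
180-2, FIPS 197 / SP 800-38A, RFC 4648) and cross-validated in the test
suite against published standard vectors and the platform reference
implementations (`hashlib`, OpenSSL's libcrypto, stdlib `base64`).

## Worked example

```python
>>> import phicrypt as pc
>>> key = pc.derive_key("passcode")
>>> key.key_hex
'ebdb375f27f3e4ab4831efaf8dc4d28d1b1c025fcd59a3de2f6710ef88831aad'
>>> pc.verification_hash(key)
'a983169676c9fdcc852f29c013aef5f6faac345dfff472548bf93a543618d5ed'
>>> pc.verify_passcode("passcode", pc.verification_hash(key))
True
>>> pc.verify_passcode("Passcode", pc.verification_hash(key))
False
```

The first hash is the encryption key derived from the passcode
`"passcode"`; the second is the verification hash of that key — the only
one of the two a server ever stores. Note it is the hash of the key's
*hex string*, not of its raw bytes.

Field encryption, on the same key:

```python
>>> container = pc.encrypt_field("Ada Lovelace", key)   # e.g. '6Tsas9QFWppvKASgcHdbt0opOwM6iEN4'
>>> pc.decrypt_field(container, key)
'Ada Lovelace'
>>> pc.encrypt_field("", key)
''
```

The container is what the server stores: random nonce plus ciphertext,
Base64-coded, different on every call. The empty string passes through —
a visibly missing value.

The `examples/` directory holds one short runnable script per capability
(verification hash, field round trip, two-tier envelope, date offsets, the
full bulk pipeline).

## Command line

```sh
phicrypt fixtures -n 1000 --seed 42 -o demo.csv --schema-out schema.yaml
phicrypt init-keys -o sidecar.json                      # prompts for a passcode
phicrypt encrypt -i demo.csv -s schema.yaml -k sidecar.json -o enc.csv
phicrypt verify  -k sidecar.json
phicrypt decrypt -i enc.csv  -s schema.yaml -k sidecar.json -o plain.csv
phicrypt escrow-export -o escrow.json
phicrypt dateshift encode -i demo.csv -o shifted.csv \
    --base-field birth_date --date-fields visit_date -k sidecar.json
```

Passcodes are read from a hidden prompt or a file descriptor
(`--passcode-fd 3 3<passfile`), never from argv.

## What this package does not do

It protects data from the server side only: user authentication, access
logging and transport security belong to the surrounding system. Key
derivation is a single unsalted SHA-256 — faithful to the protocol it
implements — so passcode strength is the line of defense against
dictionary attack. There is no per-field MAC (ciphertext length and
missingness are visible by design), and no public-key infrastructure.
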