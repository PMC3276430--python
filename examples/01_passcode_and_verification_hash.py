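"""Derive an encryption key from a passcode and check it via the verification hash.

The server stores only the verification hash — the SHA-256 of the key's hex
form. A client can prove a typed passcode is right before decrypting, while
the server can never work back to the key.
"""

import phicrypt as pc

key = pc.derive_key("passcode")
vh = pc.verification_hash(key)

print("passcode          :", "passcode")
print("key (hex)         :", key.key_hex)
print("verification hash :", vh)
print("correct passcode verifies :", pc.verify_passcode("passcode", vh))
print("typo ('Passcode') verifies:", pc.verify_passcode("Passcode", vh))

# The hash chain is: key = SHA-256(passcode), vh = SHA-256(hex(key)).
# Only the last line is ever stored server-side; both checks above ran
# entirely client-side against it.
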