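"""Encrypt and decrypt individual field values; see what the server would store.

Each non-empty value becomes Base64(nonce || AES-256-CTR ciphertext) under a
fresh random nonce. Empty values stay empty — missingness is visible without
the key, by design.
"""

import phicrypt as pc

key = pc.derive_key("hunter2")

for plaintext in ["Ada Lovelace", "(617) 555-0100", "日本語テキスト", ""]:
    container = pc.encrypt_field(plaintext, key)
    restored = pc.decrypt_field(container, key)
    print(f"{plaintext!r:30} -> {container!r:48} -> {restored!r}")

# The middle column is all the server ever sees. Note the empty string maps
# to the empty string, and the container length grows with the plaintext
# (a documented property of CTR mode: length is not hidden).
wrong = pc.derive_key("wrong passcode")
try:
    pc.decrypt_field(pc.encrypt_field("日本語テキスト", key), wrong)
except pc.IntegrityError as exc:
    print("wrong key ->", exc)
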