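"""Two-tier access: a participant passcode and a site passcode unlock the same data.

The participant's key encrypts the data; that key is itself encrypted
("wrapped") under the site key. The server stores both verification hashes
and the wrapped key — enough for either party to unlock, never enough to
decrypt.
"""

import phicrypt as pc

envelope = pc.wrap_key("my-own-secret", "site-shared-secret")

print("participant verification hash:", envelope.participant_vh)
print("site verification hash       :", envelope.site_vh)
print("wrapped participant key      :", envelope.wrapped_key)

k_participant = pc.unwrap_key(envelope, "my-own-secret", role="participant")
k_site = pc.unwrap_key(envelope, "site-shared-secret", role="site")
print("both paths yield the same key:", k_participant == k_site)

# Tampering with the stored wrapped key is always caught, because the
# recovered key must hash back to the participant verification hash.
import dataclasses

mutated = envelope.wrapped_key[:-5] + ("A" if envelope.wrapped_key[-5] != "A" else "B") + envelope.wrapped_key[-4:]
bad = dataclasses.replace(envelope, wrapped_key=mutated)
try:
    pc.unwrap_key(bad, "site-shared-secret", role="site")
except (pc.TamperError, pc.FormatError) as exc:
    print("tampered envelope ->", type(exc).__name__, "-", exc)

# Escrow: the sealed-envelope deposit a site can lodge with a neutral agent.
bundle = pc.escrow_export("site-shared-secret")
print("escrow bundle self-consistent:", bundle.check())
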