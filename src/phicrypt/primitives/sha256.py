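"""SHA-256 (FIPS 180-2), implemented from the standard.

The package carries its own implementation so the whole encryption path is
auditable in one place; the test suite cross-checks it against the platform
``hashlib`` on published vectors and random inputs.
"""

from __future__ import annotations

import struct

__all__ = ["sha256_bytes", "sha256_hex"]

# First 32 bits of the fractional parts of the cube roots of the first 64
# primes (FIPS 180-2 round constants).
_K = (
    0x428A2F98, 0x71374491, 0xB5C0FBCF, 0xE9B5DBA5,
    0x3956C25B, 0x59F111F1, 0x923F82A4, 0xAB1C5ED5,
    0xD807AA98, 0x12835B01, 0x243185BE, 0x550C7DC3,
    0x72BE5D74, 0x80DEB1FE, 0x9BDC06A7, 0xC19BF174,
    0xE49B69C1, 0xEFBE4786, 0x0FC19DC6, 0x240CA1CC,
    0x2DE92C6F, 0x4A7484AA, 0x5CB0A9DC, 0x76F988DA,
    0x983E5152, 0xA831C66D, 0xB00327C8, 0xBF597FC7,
    0xC6E00BF3, 0xD5A79147, 0x06CA6351, 0x14292967,
    0x27B70A85, 0x2E1B2138, 0x4D2C6DFC, 0x53380D13,
    0x650A7354, 0x766A0ABB, 0x81C2C92E, 0x92722C85,
    0xA2BFE8A1, 0xA81A664B, 0xC24B8B70, 0xC76C51A3,
    0xD192E819, 0xD6990624, 0xF40E3585, 0x106AA070,
    0x19A4C116, 0x1E376C08, 0x2748774C, 0x34B0BCB5,
    0x391C0CB3, 0x4ED8AA4A, 0x5B9CCA4F, 0x682E6FF3,
    0x748F82EE, 0x78A5636F, 0x84C87814, 0x8CC70208,
    0x90BEFFFA, 0xA4506CEB, 0xBEF9A3F7, 0xC67178F2,
)

# Initial hash value: fractional parts of the square roots of the first 8 primes.
_H0 = (
    0x6A09E667, 0xBB67AE85, 0x3C6EF372, 0xA54FF53A,
    0x510E527F, 0x9B05688C, 0x1F83D9AB, 0x5BE0CD19,
)

_MASK = 0xFFFFFFFF


def _rotr(x: int, n: int) -> int:
    return ((x >> n) | (x << (32 - n))) & _MASK


def _compress(state: list[int], block: bytes) -> None:
    w = list(struct.unpack(">16I", block))
    for t in range(16, 64):
        s0 = _rotr(w[t - 15], 7) ^ _rotr(w[t - 15], 18) ^ (w[t - 15] >> 3)
        s1 = _rotr(w[t - 2], 17) ^ _rotr(w[t - 2], 19) ^ (w[t - 2] >> 10)
        w.append((w[t - 16] + s0 + w[t - 7] + s1) & _MASK)

    a, b, c, d, e, f, g, h = state
    for t in range(64):
        big_s1 = _rotr(e, 6) ^ _rotr(e, 11) ^ _rotr(e, 25)
        ch = (e & f) ^ (~e & g)
        t1 = (h + big_s1 + ch + _K[t] + w[t]) & _MASK
        big_s0 = _rotr(a, 2) ^ _rotr(a, 13) ^ _rotr(a, 22)
        maj = (a & b) ^ (a & c) ^ (b & c)
        t2 = (big_s0 + maj) & _MASK
        h, g, f, e, d, c, b, a = g, f, e, (d + t1) & _MASK, c, b, a, (t1 + t2) & _MASK

    state[0] = (state[0] + a) & _MASK
    state[1] = (state[1] + b) & _MASK
    state[2] = (state[2] + c) & _MASK
    state[3] = (state[3] + d) & _MASK
    state[4] = (state[4] + e) & _MASK
    state[5] = (state[5] + f) & _MASK
    state[6] = (state[6] + g) & _MASK
    state[7] = (state[7] + h) & _MASK


def sha256_bytes(message: bytes) -> bytes:
    """Return the 32-byte SHA-256 digest of *message*."""
    if not isinstance(message, (bytes, bytearray, memoryview)):
        raise TypeError("sha256 input must be bytes")
    message = bytes(message)
    bit_len = len(message) * 8
    # Pad: one 0x80 byte, zeros, then the 64-bit big-endian message length.
    padded = message + b"\x80"
    padded += b"\x00" * ((56 - len(padded)) % 64)
    padded += struct.pack(">Q", bit_len)

    state = list(_H0)
    for off in range(0, len(padded), 64):
        _compress(state, padded[off : off + 64])
    return struct.pack(">8I", *state)


def sha256_hex(message: bytes) -> str:
    """SHA-256 digest of *message* as 64 lowercase hex characters."""
    return sha256_bytes(message).hex()
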