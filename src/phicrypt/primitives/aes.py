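"""AES-256 block cipher and counter mode (FIPS 197 / SP 800-38A).

The substitution box and the round-transform lookup tables are generated
from the GF(2^8) arithmetic the standard defines rather than transcribed,
and the whole cipher is expressed over numpy ``uint32`` arrays so that a
counter-mode keystream for N blocks is computed in one vectorised pass.
Single-block encryption and decryption reuse the same core at N = 1.

Counter-block layout (this package's definition): a 12-octet nonce followed
by a 32-bit big-endian block counter starting at 0, i.e. the 16-octet
counter block for block *i* is ``nonce || i``. Messages are therefore
limited to 2^32 blocks under one (key, nonce) pair.
"""

from __future__ import annotations

import struct
from functools import lru_cache

import numpy as np

__all__ = ["aes256_encrypt_block", "aes256_decrypt_block", "ctr_crypt", "NONCE_LEN"]

NONCE_LEN = 12
_NR = 14  # rounds for a 256-bit key


# --- GF(2^8) arithmetic and table generation -------------------------------

def _build_gf_tables() -> tuple[list[int], list[int]]:
    """exp/log tables for GF(2^8) with the AES polynomial x^8+x^4+x^3+x+1."""
    exp = [0] * 512
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        # multiply by 0x03 (a generator): x*2 ^ x, reduced mod 0x11b
        x ^= ((x << 1) ^ (0x11B if x & 0x80 else 0))
        x &= 0xFF
    for i in range(255, 512):
        exp[i] = exp[i - 255]
    return exp, log


_EXP, _LOG = _build_gf_tables()


def _gmul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def _build_sbox() -> tuple[list[int], list[int]]:
    sbox = [0] * 256
    for b in range(256):
        inv = 0 if b == 0 else _EXP[255 - _LOG[b]]
        s = inv
        r = inv
        for _ in range(4):
            r = ((r << 1) | (r >> 7)) & 0xFF
            s ^= r
        sbox[b] = s ^ 0x63
    inv_sbox = [0] * 256
    for b, s in enumerate(sbox):
        inv_sbox[s] = b
    return sbox, inv_sbox


_SBOX_LIST, _INV_SBOX_LIST = _build_sbox()


def _word(b0: int, b1: int, b2: int, b3: int) -> int:
    return (b0 << 24) | (b1 << 16) | (b2 << 8) | b3


def _build_round_tables():
    """T-tables: Te_i combine SubBytes, ShiftRows and MixColumns per byte
    position; Td_i the inverse transform for the equivalent inverse cipher."""
    te = [np.zeros(256, dtype=np.uint32) for _ in range(4)]
    td = [np.zeros(256, dtype=np.uint32) for _ in range(4)]
    for x in range(256):
        s = _SBOX_LIST[x]
        w = _word(_gmul(s, 2), s, s, _gmul(s, 3))
        for i in range(4):
            te[i][x] = ((w >> (8 * i)) | (w << (32 - 8 * i))) & 0xFFFFFFFF
        si = _INV_SBOX_LIST[x]
        wd = _word(_gmul(si, 0x0E), _gmul(si, 0x09), _gmul(si, 0x0D), _gmul(si, 0x0B))
        for i in range(4):
            td[i][x] = ((wd >> (8 * i)) | (wd << (32 - 8 * i))) & 0xFFFFFFFF
    return te, td


(_TE0, _TE1, _TE2, _TE3), (_TD0, _TD1, _TD2, _TD3) = _build_round_tables()
_SBOX = np.array(_SBOX_LIST, dtype=np.uint32)
_INV_SBOX = np.array(_INV_SBOX_LIST, dtype=np.uint32)
_RCON = (0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40)


# --- key schedule -----------------------------------------------------------

def _sub_word(w: int) -> int:
    return _word(
        _SBOX_LIST[(w >> 24) & 0xFF],
        _SBOX_LIST[(w >> 16) & 0xFF],
        _SBOX_LIST[(w >> 8) & 0xFF],
        _SBOX_LIST[w & 0xFF],
    )


def _inv_mix_word(w: int) -> int:
    # InvMixColumns of a round-key word, via Td o SubBytes (the Td tables
    # fold InvSubBytes in, so feeding them SubBytes(byte) isolates the
    # column mix).
    return int(
        _TD0[_SBOX_LIST[(w >> 24) & 0xFF]]
        ^ _TD1[_SBOX_LIST[(w >> 16) & 0xFF]]
        ^ _TD2[_SBOX_LIST[(w >> 8) & 0xFF]]
        ^ _TD3[_SBOX_LIST[w & 0xFF]]
    )


@lru_cache(maxsize=128)
def _expand_key(key: bytes) -> tuple[np.ndarray, np.ndarray]:
    """Return (encryption round keys, decryption round keys) as uint32 arrays
    of 4*(NR+1) words each."""
    if len(key) != 32:
        raise ValueError(f"AES-256 key must be 32 octets, got {len(key)}")
    w = list(struct.unpack(">8I", key))
    for i in range(8, 4 * (_NR + 1)):
        t = w[i - 1]
        if i % 8 == 0:
            t = _sub_word(((t << 8) | (t >> 24)) & 0xFFFFFFFF) ^ (_RCON[i // 8 - 1] << 24)
        elif i % 8 == 4:
            t = _sub_word(t)
        w.append(w[i - 8] ^ t)

    # Equivalent inverse cipher: reverse round order, InvMixColumns on the
    # inner rounds' keys.
    dw = [0] * len(w)
    for r in range(_NR + 1):
        for i in range(4):
            dw[4 * r + i] = w[4 * (_NR - r) + i]
    for r in range(1, _NR):
        for i in range(4):
            dw[4 * r + i] = _inv_mix_word(dw[4 * r + i])
    return np.array(w, dtype=np.uint32), np.array(dw, dtype=np.uint32)


# --- block transforms over word-column arrays ------------------------------

def _encrypt_words(rk: np.ndarray, s0, s1, s2, s3):
    s0 = s0 ^ rk[0]
    s1 = s1 ^ rk[1]
    s2 = s2 ^ rk[2]
    s3 = s3 ^ rk[3]
    for r in range(1, _NR):
        k = 4 * r
        t0 = _TE0[s0 >> 24] ^ _TE1[(s1 >> 16) & 0xFF] ^ _TE2[(s2 >> 8) & 0xFF] ^ _TE3[s3 & 0xFF] ^ rk[k]
        t1 = _TE0[s1 >> 24] ^ _TE1[(s2 >> 16) & 0xFF] ^ _TE2[(s3 >> 8) & 0xFF] ^ _TE3[s0 & 0xFF] ^ rk[k + 1]
        t2 = _TE0[s2 >> 24] ^ _TE1[(s3 >> 16) & 0xFF] ^ _TE2[(s0 >> 8) & 0xFF] ^ _TE3[s1 & 0xFF] ^ rk[k + 2]
        t3 = _TE0[s3 >> 24] ^ _TE1[(s0 >> 16) & 0xFF] ^ _TE2[(s1 >> 8) & 0xFF] ^ _TE3[s2 & 0xFF] ^ rk[k + 3]
        s0, s1, s2, s3 = t0, t1, t2, t3
    k = 4 * _NR
    o0 = (_SBOX[s0 >> 24] << 24) ^ (_SBOX[(s1 >> 16) & 0xFF] << 16) ^ (_SBOX[(s2 >> 8) & 0xFF] << 8) ^ _SBOX[s3 & 0xFF] ^ rk[k]
    o1 = (_SBOX[s1 >> 24] << 24) ^ (_SBOX[(s2 >> 16) & 0xFF] << 16) ^ (_SBOX[(s3 >> 8) & 0xFF] << 8) ^ _SBOX[s0 & 0xFF] ^ rk[k + 1]
    o2 = (_SBOX[s2 >> 24] << 24) ^ (_SBOX[(s3 >> 16) & 0xFF] << 16) ^ (_SBOX[(s0 >> 8) & 0xFF] << 8) ^ _SBOX[s1 & 0xFF] ^ rk[k + 2]
    o3 = (_SBOX[s3 >> 24] << 24) ^ (_SBOX[(s0 >> 16) & 0xFF] << 16) ^ (_SBOX[(s1 >> 8) & 0xFF] << 8) ^ _SBOX[s2 & 0xFF] ^ rk[k + 3]
    return o0, o1, o2, o3


def _decrypt_words(dk: np.ndarray, s0, s1, s2, s3):
    s0 = s0 ^ dk[0]
    s1 = s1 ^ dk[1]
    s2 = s2 ^ dk[2]
    s3 = s3 ^ dk[3]
    for r in range(1, _NR):
        k = 4 * r
        t0 = _TD0[s0 >> 24] ^ _TD1[(s3 >> 16) & 0xFF] ^ _TD2[(s2 >> 8) & 0xFF] ^ _TD3[s1 & 0xFF] ^ dk[k]
        t1 = _TD0[s1 >> 24] ^ _TD1[(s0 >> 16) & 0xFF] ^ _TD2[(s3 >> 8) & 0xFF] ^ _TD3[s2 & 0xFF] ^ dk[k + 1]
        t2 = _TD0[s2 >> 24] ^ _TD1[(s1 >> 16) & 0xFF] ^ _TD2[(s0 >> 8) & 0xFF] ^ _TD3[s3 & 0xFF] ^ dk[k + 2]
        t3 = _TD0[s3 >> 24] ^ _TD1[(s2 >> 16) & 0xFF] ^ _TD2[(s1 >> 8) & 0xFF] ^ _TD3[s0 & 0xFF] ^ dk[k + 3]
        s0, s1, s2, s3 = t0, t1, t2, t3
    k = 4 * _NR
    o0 = (_INV_SBOX[s0 >> 24] << 24) ^ (_INV_SBOX[(s3 >> 16) & 0xFF] << 16) ^ (_INV_SBOX[(s2 >> 8) & 0xFF] << 8) ^ _INV_SBOX[s1 & 0xFF] ^ dk[k]
    o1 = (_INV_SBOX[s1 >> 24] << 24) ^ (_INV_SBOX[(s0 >> 16) & 0xFF] << 16) ^ (_INV_SBOX[(s3 >> 8) & 0xFF] << 8) ^ _INV_SBOX[s2 & 0xFF] ^ dk[k + 1]
    o2 = (_INV_SBOX[s2 >> 24] << 24) ^ (_INV_SBOX[(s1 >> 16) & 0xFF] << 16) ^ (_INV_SBOX[(s0 >> 8) & 0xFF] << 8) ^ _INV_SBOX[s3 & 0xFF] ^ dk[k + 2]
    o3 = (_INV_SBOX[s3 >> 24] << 24) ^ (_INV_SBOX[(s2 >> 16) & 0xFF] << 16) ^ (_INV_SBOX[(s1 >> 8) & 0xFF] << 8) ^ _INV_SBOX[s0 & 0xFF] ^ dk[k + 3]
    return o0, o1, o2, o3


def _block_to_words(block: bytes):
    w = np.frombuffer(block, dtype=">u4").astype(np.uint32)
    return w[0::4], w[1::4], w[2::4], w[3::4]


def _words_to_bytes(w0, w1, w2, w3) -> bytes:
    return np.stack([w0, w1, w2, w3], axis=-1).astype(">u4").tobytes()


# --- public operations ------------------------------------------------------

def aes256_encrypt_block(key: bytes, block: bytes) -> bytes:
    """Encrypt a single 16-octet block under a 32-octet key."""
    if len(block) != 16:
        raise ValueError(f"AES block must be 16 octets, got {len(block)}")
    rk, _ = _expand_key(bytes(key))
    return _words_to_bytes(*_encrypt_words(rk, *_block_to_words(bytes(block))))


def aes256_decrypt_block(key: bytes, block: bytes) -> bytes:
    """Decrypt a single 16-octet block under a 32-octet key."""
    if len(block) != 16:
        raise ValueError(f"AES block must be 16 octets, got {len(block)}")
    _, dk = _expand_key(bytes(key))
    return _words_to_bytes(*_decrypt_words(dk, *_block_to_words(bytes(block))))


def ctr_crypt(key: bytes, nonce: bytes, data: bytes) -> bytes:
    """Encrypt or decrypt *data* in counter mode (the same XOR either way).

    Keystream block *i* is the AES-256 encryption of ``nonce || i`` with the
    counter as a 32-bit big-endian integer starting at 0.
    """
    if len(nonce) != NONCE_LEN:
        raise ValueError(f"nonce must be {NONCE_LEN} octets, got {len(nonce)}")
    data = bytes(data)
    if not data:
        return b""
    nblocks = -(-len(data) // 16)
    if nblocks > 2**32:
        raise ValueError("message exceeds 2^32 blocks for one nonce")
    rk, _ = _expand_key(bytes(key))
    n0, n1, n2 = struct.unpack(">3I", nonce)
    s0 = np.full(nblocks, n0, dtype=np.uint32)
    s1 = np.full(nblocks, n1, dtype=np.uint32)
    s2 = np.full(nblocks, n2, dtype=np.uint32)
    s3 = np.arange(nblocks, dtype=np.uint32)
    keystream = _words_to_bytes(*_encrypt_words(rk, s0, s1, s2, s3))
    buf = np.frombuffer(data, dtype=np.uint8) ^ np.frombuffer(keystream[: len(data)], dtype=np.uint8)
    return buf.tobytes()
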