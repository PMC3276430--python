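"""Platform reference implementations used as independent oracles.

These never touch phicrypt's own primitives: SHA-256 via hashlib, Base64
via the stdlib codec, AES via OpenSSL's libcrypto reached over ctypes.
"""

from __future__ import annotations

import base64 as _stdlib_base64
import ctypes
import ctypes.util
import hashlib


def sha256_hex_oracle(message: bytes) -> str:
    return hashlib.sha256(message).hexdigest()


def b64_encode_oracle(data: bytes) -> str:
    return _stdlib_base64.b64encode(data).decode("ascii")


def b64_decode_oracle(text: str) -> bytes:
    return _stdlib_base64.b64decode(text, validate=True)


class _LibCrypto:
    def __init__(self) -> None:
        name = ctypes.util.find_library("crypto")
        self.lib = ctypes.CDLL(name)
        self.lib.EVP_CIPHER_CTX_new.restype = ctypes.c_void_p
        self.lib.EVP_CIPHER_CTX_free.argtypes = [ctypes.c_void_p]
        self.lib.EVP_aes_256_ecb.restype = ctypes.c_void_p
        self.lib.EVP_aes_256_ctr.restype = ctypes.c_void_p

    def _crypt(self, cipher, key: bytes, iv: bytes | None, data: bytes) -> bytes:
        lib = self.lib
        ctx = lib.EVP_CIPHER_CTX_new()
        try:
            ok = lib.EVP_EncryptInit_ex(
                ctypes.c_void_p(ctx), ctypes.c_void_p(cipher), None, key, iv
            )
            assert ok == 1
            lib.EVP_CIPHER_CTX_set_padding(ctypes.c_void_p(ctx), 0)
            out = ctypes.create_string_buffer(len(data) + 16)
            outlen = ctypes.c_int(0)
            ok = lib.EVP_EncryptUpdate(
                ctypes.c_void_p(ctx), out, ctypes.byref(outlen), data, len(data)
            )
            assert ok == 1
            return out.raw[: outlen.value]
        finally:
            lib.EVP_CIPHER_CTX_free(ctypes.c_void_p(ctx))

    def aes256_ecb_encrypt(self, key: bytes, data: bytes) -> bytes:
        return self._crypt(self.lib.EVP_aes_256_ecb(), key, None, data)

    def aes256_ctr(self, key: bytes, nonce12: bytes, data: bytes) -> bytes:
        # OpenSSL CTR increments the whole 128-bit big-endian block; with a
        # zero 4-byte tail this matches a 32-bit counter for < 2^32 blocks.
        return self._crypt(self.lib.EVP_aes_256_ctr(), key, nonce12 + b"\x00" * 4, data)


_libcrypto = None


def libcrypto() -> _LibCrypto:
    global _libcrypto
    if _libcrypto is None:
        _libcrypto = _LibCrypto()
    return _libcrypto


def aes256_encrypt_block_oracle(key: bytes, block: bytes) -> bytes:
    return libcrypto().aes256_ecb_encrypt(key, block)


def ctr_crypt_oracle(key: bytes, nonce: bytes, data: bytes) -> bytes:
    return libcrypto().aes256_ctr(key, nonce, data)
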