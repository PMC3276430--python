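"""Exception hierarchy.

Every error raised by this package derives from :class:`PhicryptError`, so
callers embedding the library can catch one type at the boundary.
"""


class PhicryptError(Exception):
    """Base class for all errors raised by phicrypt."""


class ValidationError(PhicryptError):
    """An input violates a precondition (empty passcode, bad date, ...)."""


class ConfigurationError(PhicryptError):
    """Required configuration is absent, e.g. no verification hash on file."""


class AuthenticationError(PhicryptError):
    """A passcode failed its verification-hash check.

    Attributes
    ----------
    which : str
        Name of the hash that failed ("participant" or "site").
    record
        When raised by record-level decryption, the record with its
        protected fields locked; ciphertext is never modified on failure.
    """

    def __init__(self, message: str, *, which: str = "participant", record=None):
        super().__init__(message)
        self.which = which
        self.record = record


class TamperError(PhicryptError):
    """Decrypted material is structurally invalid — corruption or tampering."""


class FormatError(PhicryptError):
    """A cipher container or file is malformed (bad Base64, short container)."""


class IntegrityError(PhicryptError):
    """Decryption produced implausible plaintext — wrong key or corruption."""


class SchemaError(PhicryptError):
    """Dataset columns do not match the declared schema."""


class LeakPreventionError(PhicryptError):
    """A server-bound projection would expose protected plaintext."""
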