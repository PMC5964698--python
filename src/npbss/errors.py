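"""Exception hierarchy shared across the package."""


class NpbssError(Exception):
    """Base class for all package-specific errors."""


class InputError(NpbssError):
    """A required input file is missing or unreadable."""


class FormatError(NpbssError, ValueError):
    """An input file violates its expected format."""


class ConfigError(NpbssError, ValueError):
    """A simulation configuration is inconsistent or unresolvable."""


class EncodingError(NpbssError, ValueError):
    """A quality value cannot be encoded in Phred+33 FASTQ."""
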