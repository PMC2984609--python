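"""Exception hierarchy.

The CLI maps :class:`ConfigError`/:class:`ValidationError` to exit code 2 and
:class:`FormatError` to exit code 3.
"""


class GendoseError(Exception):
    """Base class for all package errors."""


class ConfigError(GendoseError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(GendoseError):
    """Invalid input data (phenotype table, panel, degenerate fits)."""


class FormatError(GendoseError):
    """Malformed genotype file (PLINK/VCF); the message names the file."""
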