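"""Typed exceptions shared across the package."""


class CadrdvpError(Exception):
    """Base class for all package errors."""


class ConfigError(CadrdvpError):
    """Invalid configuration value; message names the offending field."""


class ValidationError(CadrdvpError):
    """A data contract was violated (duplicate ids, bad ranges, ...)."""


class ParseError(CadrdvpError):
    """A file could not be parsed; message carries path and line context."""
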