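"""Exception taxonomy.

``InputError`` subclasses map to CLI exit code 1 (bad user input); everything
else that escapes maps to exit code 2.
"""


class RxnliftError(Exception):
    """Base class for all package errors."""


class InputError(RxnliftError):
    """The user supplied something unusable (file, SMILES, flag value)."""


class FormatError(InputError):
    """A file or string has the wrong shape (columns, '>' parts, ...)."""


class ParseError(InputError):
    """A token inside an otherwise well-shaped input does not parse."""


class ConfigError(InputError):
    """An invalid configuration object (fixture templates, params)."""


class IntegrityError(RxnliftError):
    """Internal consistency violated (e.g. occurrence indexes out of range)."""


class UnsupportedActivationError(RxnliftError):
    """Attribution requested for an activation the Rescale rule engine
    does not implement."""
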