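"""Exception hierarchy shared across the package.

Two failure classes are distinguished so that callers (and the CLI exit
codes) can separate "your configuration is wrong" from "your data is
unusable".
"""


class PulseQCError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PulseQCError):
    """A parameter, config file or ruleset is invalid (CLI exit code 2)."""


class InputError(PulseQCError):
    """The input data violate a precondition (CLI exit code 3)."""
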