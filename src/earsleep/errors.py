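"""Exception hierarchy shared across the package.

Two broad failure classes matter to callers: malformed or inconsistent
*input* (bad files, unknown stage labels, mismatched lengths) and
*degenerate data* that makes a quantity undefined (constant signals,
zero in-band power, single-class label sets).  The command-line layer
maps these onto distinct exit codes.
"""


class EarsleepError(Exception):
    """Base class for all package-specific errors."""


class InputError(EarsleepError):
    """Malformed, inconsistent, or missing input (file or argument)."""


class DegenerateDataError(EarsleepError):
    """Data for which the requested quantity is mathematically undefined."""
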