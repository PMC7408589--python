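"""Exception hierarchy shared across the package.

``InputError`` maps to CLI exit code 1 (bad or inconsistent input),
``NumericalError`` to exit code 2 (a computation failed or is undefined
for the given data).
"""


class RadassayError(Exception):
    """Base class for all package errors."""


class InputError(RadassayError, ValueError):
    """Invalid, missing or inconsistent input data/configuration."""


class NumericalError(RadassayError, RuntimeError):
    """A numerical procedure failed or is undefined for the data."""
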