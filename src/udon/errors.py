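"""Exception hierarchy.

``InputError`` marks problems with user-supplied data (schema, missing
references, degenerate cohorts) and maps to CLI exit code 1; every other
``UdonError`` maps to exit code 2.
"""


class UdonError(Exception):
    """Base class for all errors raised by this package."""


class InputError(UdonError):
    """Invalid or inconsistent user input (data, annotation, config)."""
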