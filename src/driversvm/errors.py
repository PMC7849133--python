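"""Exception hierarchy.

``InputError`` marks problems with user-supplied data (bad schema, unknown
vocabulary, missing files); anything else raised by the package is a runtime
failure.  The CLI maps the two onto exit codes 1 and 2 respectively.
"""


class DriverSVMError(Exception):
    """Base class for package errors."""


class InputError(DriverSVMError):
    """Invalid or inconsistent user input."""
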