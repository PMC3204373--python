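"""Exception hierarchy.

``ConfigurationError`` marks invalid model/hyper-parameter settings
(non-positive time constants, learning rate out of range, ...);
``InputError`` marks invalid data passed to an operation (mismatched
train lengths, negative distances, ...). Both derive from ``ValueError``
so callers that do not care about the distinction can catch broadly.
"""


class DynSynError(Exception):
    """Base class for all dynsynrl errors."""


class ConfigurationError(DynSynError, ValueError):
    """A parameter or configuration value is invalid."""


class InputError(DynSynError, ValueError):
    """Input data violates a precondition of an operation."""
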