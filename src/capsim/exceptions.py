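"""Exception hierarchy.

``ValidationError`` covers malformed domain objects and inputs (bad lengths,
unsorted trains, networks violating node-kind rules); ``ConfigurationError``
covers inconsistent run parameters (e.g. a fusion tolerance not smaller than
the refractory period, or an oracle time step too coarse for the tolerance).
"""


class CapsimError(Exception):
    """Base class for all capsim errors."""


class ValidationError(CapsimError, ValueError):
    """Domain object or input data violates an invariant."""


class ConfigurationError(CapsimError, ValueError):
    """Run parameters are mutually inconsistent."""
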