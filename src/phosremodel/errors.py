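"""Exception hierarchy.

All package-raised errors derive from :class:`PhosremodelError` so callers
can catch one base class; the CLI maps subclasses onto exit codes.
"""


class PhosremodelError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PhosremodelError):
    """A configuration object is internally inconsistent."""


class FormatError(PhosremodelError):
    """An input file does not conform to the expected tabular format."""


class DesignError(PhosremodelError):
    """The sample design does not support the requested operation."""


class InputError(PhosremodelError):
    """Operation arguments violate a precondition."""
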