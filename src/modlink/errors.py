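"""Exception hierarchy for the pipeline.

All errors raised on invalid user input derive from :class:`ModlinkError`
so callers (and the CLI) can catch one base class.
"""


class ModlinkError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(ModlinkError, ValueError):
    """A configuration object violates one of its invariants."""


class FormatError(ModlinkError, ValueError):
    """An input file does not conform to its documented format."""


class ValidationError(ModlinkError, ValueError):
    """An in-memory container violates one of its invariants."""
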