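"""Exception hierarchy shared by all marpipe modules.

Every error raised on bad user input derives from :class:`MarpipeError`, so
callers (and the CLI) can distinguish pipeline errors from programming bugs.
"""


class MarpipeError(Exception):
    """Base class for all marpipe errors."""


class ParseError(MarpipeError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}: "
        if line is not None:
            loc += f"line {line}: "
        super().__init__(loc + message)
        self.path = path
        self.line = line


class ValidationError(MarpipeError):
    """Structurally valid input violating a semantic constraint."""


class ConfigurationError(MarpipeError):
    """A parameter or grid/gate configuration violates its invariants."""


class DegenerateInputError(MarpipeError):
    """Input that makes the requested quantity undefined (e.g. zero totals)."""


class CapacityError(MarpipeError):
    """A synthetic layout cannot be realised (e.g. intervals do not fit)."""


class NoAmplificationError(MarpipeError):
    """A qPCR curve shows no usable exponential phase."""


class EfficiencyOutOfRangeError(MarpipeError):
    """Estimated qPCR efficiency outside the plausible (1, 2.2] range."""


class NoCtError(MarpipeError):
    """A qPCR curve never crosses the chosen fluorescence threshold."""
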