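"""Exception hierarchy.

Every error raised by fluctnet derives from :class:`FluctnetError` so callers
(and the CLI, which maps error classes onto exit codes) can distinguish
configuration problems, unreadable inputs, and genuine analysis degeneracies.
"""


class FluctnetError(Exception):
    """Base class for all fluctnet errors."""


class ConfigError(FluctnetError):
    """Invalid, incomplete, or contradictory configuration."""


class FormatError(FluctnetError):
    """Unreadable or malformed input file."""


class EmptySelectionError(FluctnetError):
    """An atom selection matched zero atoms."""


class ConsistencyError(FluctnetError):
    """Inputs that are individually valid but mutually inconsistent."""


class ResidueLookupError(FluctnetError, KeyError):
    """A residue key was not found in the residue table or graph."""


class DegenerateVarianceError(FluctnetError):
    """A residue with zero positional variance; correlation undefined."""


class DisconnectionError(FluctnetError):
    """No path connects the requested source and sink regions."""


class DegeneracyError(FluctnetError):
    """A spring graph whose covariance pseudo-inverse is block-degenerate."""


class ComparisonError(FluctnetError):
    """Analysis bundles produced with different settings cannot be compared."""
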