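"""Exception hierarchy for wormhcs.

All pipeline errors derive from :class:`WormHCSError` so callers can catch
everything from one place; the CLI maps configuration errors to exit code 2
and data errors to exit code 3.
"""


class WormHCSError(Exception):
    """Base class for all wormhcs errors."""


class ConfigurationError(WormHCSError):
    """Invalid configuration: unknown channel, overlapping control columns, bad paths."""


class CalibrationError(WormHCSError):
    """A gate or threshold could not be calibrated (too few references, empty masks)."""


class DataError(WormHCSError):
    """Input data violate a precondition (empty plate, missing channel, ...)."""


class UndefinedStatisticError(WormHCSError):
    """A statistic is undefined for the given inputs (zero SD, equal control means)."""


class DegeneratePlateError(WormHCSError):
    """Plate is unanalyzable: residual MAD at or below the floor."""
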