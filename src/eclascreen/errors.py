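"""Exception hierarchy shared across the package."""


class EclaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EclaError):
    """A spot-table file does not conform to the GPR dialect (e.g. a missing column)."""


class IntegrityError(EclaError):
    """Structurally inconsistent data: duplicate grid positions, mismatched grids."""


class CapacityError(EclaError):
    """A layout cannot hold the requested clones with the given block geometry."""


class ConfigurationError(EclaError):
    """Invalid configuration: missing conditions, unknown planted names, bad thresholds."""


class InsufficientDataError(EclaError):
    """Too few observations for the requested statistic."""


class SpotExcludedError(EclaError):
    """The spot is flag-excluded and has no numeric net intensity."""
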