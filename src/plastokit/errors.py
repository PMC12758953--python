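"""Exception hierarchy shared across the toolkit."""


class PlastokitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(PlastokitError):
    """Malformed or unsupported input file."""


class CoordinateError(PlastokitError):
    """Feature coordinates inconsistent with the sequence they annotate."""


class QuadripartiteError(PlastokitError):
    """No valid LSC/SSC/IR partition could be derived."""


class AlignmentError(PlastokitError):
    """Pairwise alignment could not be produced as requested."""


class ConfigError(PlastokitError):
    """Invalid configuration (thresholds, parameters, CLI usage)."""


class SimulationError(PlastokitError):
    """Synthetic-genome parameters are infeasible."""
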