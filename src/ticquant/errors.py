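"""Exception hierarchy shared across the pipeline.

Config/parameter problems map to CLI exit code 2, data/format/design
problems to exit code 3 (see :mod:`ticquant.cli`).
"""


class TicquantError(Exception):
    """Base class for all ticquant errors."""


class ConfigError(TicquantError):
    """Invalid run configuration (bad paths, inconsistent design, bad thresholds)."""


class ParameterError(TicquantError):
    """Invalid argument to a computation (negative cutoff, non-positive mass...)."""


class FormatError(TicquantError):
    """Malformed input file (missing column, non-numeric field, bad MGF block)."""


class DesignError(TicquantError):
    """Sample design incompatible with the requested procedure."""


class StatisticsError(TicquantError):
    """Population too small for the requested statistic."""


class DegeneratePopulationError(StatisticsError):
    """Zero-variance population: the statistic is undefined."""
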