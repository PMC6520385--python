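"""Error hierarchy. Each family maps to a distinct CLI exit code."""


class PropensityScreenError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PropensityScreenError):
    """Invalid configuration (bad counts, infeasible coupling, bad thresholds)."""

    exit_code = 2


class FormatError(PropensityScreenError):
    """Malformed input file (missing columns, duplicate ids, non-numeric cells)."""

    exit_code = 3


class AnalysisError(PropensityScreenError):
    """A computation's preconditions are violated (degenerate matrix, missing gene...)."""

    exit_code = 4
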