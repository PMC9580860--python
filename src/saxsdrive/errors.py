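"""Exception hierarchy used across the toolkit."""


class SaxsdriveError(Exception):
    """Base class for all toolkit errors."""


class InputError(SaxsdriveError, ValueError):
    """Invalid user-supplied argument (shapes, ranges, counts)."""


class LookupFormFactorError(SaxsdriveError, KeyError):
    """A particle label could not be resolved in the active form-factor table."""


class FormatError(SaxsdriveError, ValueError):
    """Malformed file content (profiles, structures, trajectories)."""


class FitError(SaxsdriveError, RuntimeError):
    """A regression/fit could not be carried out on the given data."""


class ConfigError(SaxsdriveError, ValueError):
    """Inconsistent restraint or run configuration."""


class SolverError(SaxsdriveError, RuntimeError):
    """Iterative optimisation failed to converge within budget."""


class IntegrityError(SaxsdriveError, RuntimeError):
    """Numerical integrity violated (NaN/Inf encountered mid-computation)."""
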