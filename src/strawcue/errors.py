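"""Exception and warning types shared across the package."""


class StrawCueError(Exception):
    """Base class for all package-specific errors."""


class DegenerateEndmembersError(StrawCueError, ValueError):
    """The two mixing endmembers coincide, so the tracer fraction is undefined."""


class MassBalanceError(StrawCueError, ValueError):
    """Fumigated-extract C does not exceed the non-fumigated background."""


class UndefinedCueError(StrawCueError, ValueError):
    """Both the biomass and respiration tracer pools are zero."""


class MissingControlError(StrawCueError, ValueError):
    """A labeled group has no matching unlabeled control arm."""


class ZeroVarianceError(StrawCueError, ValueError):
    """All observations are identical; the F statistic is undefined."""


class AlignmentError(StrawCueError, ValueError):
    """Sample keys of two inputs cannot be aligned."""


class ConfigError(StrawCueError, ValueError):
    """A run configuration violates the schema."""


class DependencyError(StrawCueError, RuntimeError):
    """A pipeline stage requires the output of a stage that was not run."""

    def __init__(self, stage: str, needs: str):
        self.stage = stage
        self.needs = needs
        super().__init__(f"stage '{stage}' requires output of disabled stage '{needs}'")


class StrawCueWarning(UserWarning):
    """Base class for package warnings (out-of-range fractions, dropped taxa...)."""


class NegativeFractionWarning(StrawCueWarning):
    """A mixing fraction fell outside [0, 1]; reported as computed."""


class ConstantTaxonWarning(StrawCueWarning):
    """A taxon with constant abundance was excluded from correlation."""
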