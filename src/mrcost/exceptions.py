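"""Exception and warning types shared across the package."""


class MRCostError(Exception):
    """Base class for all mrcost-specific errors."""


class InvalidFrequencyError(MRCostError, ValueError):
    """An allele frequency is non-finite or outside the open interval (0, 1)."""


class HarmonizationError(MRCostError, ValueError):
    """Summary statistics cannot be harmonized (e.g. duplicate SNP ids)."""


class UndefinedRatioError(MRCostError, ZeroDivisionError):
    """Wald ratio requested with a zero SNP-exposure association."""


class UndefinedHeterogeneityError(MRCostError, ValueError):
    """Cochran's Q requested with fewer than two instruments."""


class WeakInteractionError(MRCostError, ValueError):
    """Gene-by-environment model is not identified: the first-stage
    association does not vary across environment strata."""


class CollinearInstrumentsError(MRCostError, ValueError):
    """Multivariable MR design is rank deficient (conditionally weak
    instruments for one of the exposures)."""


class PipelineStageError(MRCostError, RuntimeError):
    """A pipeline stage failed; carries the stage name for machine use."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")


class OneSampleOverlapWarning(UserWarning):
    """The exposure and outcome cohorts share individuals; estimates are
    biased toward the confounded (non-IV) association."""


class DegenerateSnpWarning(UserWarning):
    """A genotype column was constant and has been excluded."""
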