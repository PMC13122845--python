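"""Exception hierarchy for load-time and analysis-time failures."""


class CraniospinalError(Exception):
    """Base class for all package errors."""


class LoadError(CraniospinalError):
    """A file could not be parsed into a valid domain object."""


class MissingVesselError(LoadError):
    pass


class FrameCountError(LoadError):
    pass


class PeriodMismatchError(LoadError):
    pass


class AnnotationError(LoadError):
    """Infusion annotations are inconsistent (ordering, nonpositive rate, out of span)."""


class EmptyTraceError(LoadError):
    pass


class NonUniformSamplingError(LoadError):
    pass


class ManifestError(LoadError):
    pass


class AnalysisError(CraniospinalError):
    """An analysis step failed on otherwise well-formed input."""


class BaselineTooShortError(AnalysisError):
    pass


class NoCardiacPeakError(AnalysisError):
    pass


class EmptyBandError(AnalysisError):
    pass


class TooFewPulsesError(AnalysisError):
    pass


class DegeneratePulseError(AnalysisError):
    pass


class NoPlateauError(AnalysisError):
    pass


class NonPositivePressureChangeError(AnalysisError):
    pass
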