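"""Typed errors raised across the package."""


class HydramolError(Exception):
    """Base class for all package errors."""


class EmptyInputError(HydramolError):
    """An input file or dataset yielded zero usable molecules."""


class ConformerError(HydramolError):
    """3D embedding failed for a molecule."""


class ForceFieldError(HydramolError):
    """The MMFF94 force field has no parameters for a molecule."""


class UnsupportedElementError(HydramolError):
    """An element falls outside the supported lone-pair/charge tables."""


class UnsupportedHybridisationError(HydramolError):
    """A heavy atom is not sp1/sp2/sp3 hybridised (e.g. hypervalent)."""


class ChargesMissingError(HydramolError):
    """Partial charges were requested before they were computed."""


class ValenceError(HydramolError):
    """An atom carries more heavy-atom neighbours than its hybridisation allows."""


class ConfigurationError(HydramolError):
    """An unknown backend or invalid configuration key was requested."""


class CalibrationError(HydramolError):
    """Water calibration produced a degenerate (zero) charge sum."""


class UndefinedCorrelationError(HydramolError):
    """Correlation requested on a zero-variance input."""


class DataError(HydramolError):
    """A dataset failed validation (wrong columns, no preparable molecules...)."""
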