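"""Exception hierarchy shared across the package."""


class CardiokitError(Exception):
    """Base class for all package-specific errors."""


class SpecError(CardiokitError, ValueError):
    """A simulation or analysis specification is invalid or self-contradictory."""


class FormatError(CardiokitError, ValueError):
    """An input file does not conform to the expected on-disk format."""


class ProtocolError(CardiokitError, ValueError):
    """A sweep protocol is missing, malformed, or mismatched between recordings."""


class AnalysisError(CardiokitError, RuntimeError):
    """An analysis step cannot produce a defined result for this input."""
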