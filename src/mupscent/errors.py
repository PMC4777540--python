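"""Exception types shared across the package."""


class MupscentError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MupscentError, ValueError):
    """Malformed or inconsistent input data."""


class UnknownBaseError(ValidationError):
    """A base symbol outside {A, C, G, T} was encountered."""


class UnknownIndividualError(MupscentError, KeyError):
    """An individual id not present in the matrix was requested."""


class UnknownSiteClassError(ValidationError):
    """A site-class label outside the recognised categories."""
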