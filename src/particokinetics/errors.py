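"""Exception and warning types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter violates its physical or structural constraints."""


class InsufficientDataError(ValueError):
    """Too few (or unusable) observations for the requested estimate."""


class UndefinedHalfTimeError(RuntimeError):
    """The system never reaches half of its initial mass/burden."""


class DurationTooShortError(InvalidParameterError):
    """Exposure duration is below the domain of validity of the accumulation factor."""


class SupersaturationWarning(UserWarning):
    """Dissolved concentration exceeds saturation solubility.

    The dissolution model's driving force changes sign here; precipitation
    kinetics are not modelled, so the condition is reported instead of being
    silently integrated.
    """


class ShortFitWindowWarning(UserWarning):
    """The observation window is shorter than one estimated half-time."""
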