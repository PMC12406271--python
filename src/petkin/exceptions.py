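"""Exception hierarchy.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`FitFailureError` -> 3, anything else -> 1.
"""


class PetkinError(Exception):
    """Base class for all petkin errors."""


class InputError(PetkinError, ValueError):
    """Malformed user input: bad time vectors, nonpositive distances, parse errors."""


class ConfigurationError(PetkinError):
    """Inconsistent simulation or run configuration (e.g. missing probe distance)."""


class RegistryError(PetkinError, KeyError):
    """Unknown preset name."""


class DegenerateModelError(PetkinError, ValueError):
    """Model parameters outside the regime the equations are defined for (k1 == k2)."""


class FitFailureError(PetkinError):
    """No optimizer start converged to a usable fit."""


class UndefinedRateError(PetkinError):
    """A weighted rate was requested for a fit whose amplitudes are all zero."""
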