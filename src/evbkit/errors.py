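"""Exception hierarchy.

Everything raised on purpose by evbkit derives from :class:`EVBKitError`,
so callers can catch one type at pipeline level.
"""


class EVBKitError(Exception):
    """Base class for all evbkit errors."""


class ConfigurationError(EVBKitError):
    """Malformed state/topology/scenario definition."""


class ValidationError(EVBKitError):
    """Invalid numerical input (e.g. an unnormalized lambda vector)."""


class ScheduleError(EVBKitError):
    """Ill-formed lambda schedule (duplicates, wrong endpoints)."""


class DataError(EVBKitError):
    """Missing or non-finite trajectory/energy data."""


class AlignmentError(EVBKitError):
    """Schedule and trajectory set do not correspond window-by-window."""


class SamplerInstabilityError(EVBKitError):
    """Langevin trajectory diverged; names the step size and force constant."""


class UndersamplingError(EVBKitError):
    """Profile bins are empty across a region needed for feature extraction."""


class NoBarrierError(EVBKitError):
    """Profile has no interior maximum separating two minima."""


class CompositionError(EVBKitError):
    """Leg profiles cannot be joined (role mismatch)."""


class FormatError(EVBKitError):
    """On-disk file does not conform to the documented dialect."""


class UnknownScenarioError(EVBKitError, KeyError):
    """Requested preset is not in the scenario registry."""
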