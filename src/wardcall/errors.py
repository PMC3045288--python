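"""Exception hierarchy for wardcall."""


class WardCallError(Exception):
    """Base class for all wardcall errors."""


class UnknownEntityError(WardCallError):
    """A referenced patient, staff member, space or call does not exist."""


class RoleError(WardCallError):
    """A staff role or call-maker role is not allowed to perform an action."""


class IllegalTransitionError(WardCallError):
    """A call-status transition outside the allowed status machine."""


class InconsistentIntervalsError(WardCallError):
    """Probability intervals with an empty intersection.

    Carries the offending sources (e.g. risk-factor names) when known.
    """

    def __init__(self, message, sources=()):
        super().__init__(message)
        self.sources = tuple(sources)


class NoCandidateError(WardCallError):
    """No staff member can be selected for a call."""


class ConfigError(WardCallError):
    """Invalid scenario, table, policy or behavior configuration."""
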