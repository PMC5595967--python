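"""Exception hierarchy; every stage failure carries well/compound context."""


class CycleprofError(Exception):
    """Base class for all cycleprof failures."""


class ValidationError(CycleprofError, ValueError):
    """Input violates a documented invariant (non-normalized fractions, ...)."""


class EmptyWellError(CycleprofError):
    """A well produced no events; flagged, never silently zeroed."""

    def __init__(self, well_id: str):
        self.well_id = well_id
        super().__init__(f"well {well_id!r} contains no events")


class GatingFailureError(CycleprofError):
    """Peak detection or gate construction failed for a well."""

    def __init__(self, message: str, well_id: str | None = None):
        self.well_id = well_id
        prefix = f"well {well_id!r}: " if well_id else ""
        super().__init__(prefix + message)


class MissingCompoundError(CycleprofError, KeyError):
    """A plate-map compound has no ground-truth / data entry."""

    def __init__(self, compound: str):
        self.compound = compound
        super().__init__(f"no entry for compound {compound!r}")


class UndefinedSeparationError(CycleprofError, ZeroDivisionError):
    """Z' factor undefined: positive and negative control means coincide."""


class InsufficientDesignError(CycleprofError, ValueError):
    """Dose-response fit requested with fewer than 4 distinct doses."""


class FlatCurveError(CycleprofError):
    """All responses equal: no EC50 exists."""
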