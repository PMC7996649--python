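"""Exception and warning types used across the package."""


class RefnetError(Exception):
    """Base class for all package errors."""


class ValidationError(RefnetError, ValueError):
    """Malformed or inconsistent input data (tables, records, matrices)."""


class SeparationError(RefnetError, RuntimeError):
    """Pseudolikelihood is unbounded: the network is empty or complete."""


class DegeneracyError(RefnetError, RuntimeError):
    """Model places its mass on near-empty/near-complete graphs.

    Carries a ``payload`` dict with diagnostic quantities (observed vs
    simulated statistics) when raised during estimation or simulation.
    """

    def __init__(self, message: str, payload: dict | None = None):
        super().__init__(message)
        self.payload = payload or {}


class QuasiSeparationWarning(UserWarning):
    """A pseudolikelihood coefficient diverged; estimates are unstable."""
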