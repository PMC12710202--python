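"""Exception hierarchy for erwsim."""


class ErwsimError(Exception):
    """Base class for all erwsim errors."""


class ParameterError(ErwsimError, ValueError):
    """A scalar parameter violates its documented constraint."""


class ForcingFormatError(ErwsimError, ValueError):
    """A forcing table does not conform to the documented dialect."""


class ConfigError(ErwsimError, ValueError):
    """A simulation configuration violates one or more invariants."""


class ChemistryError(ErwsimError, RuntimeError):
    """An aqueous-chemistry solve failed; message carries the inputs."""


class StepError(ErwsimError, RuntimeError):
    """A time step could not be completed; message carries the timestamp."""


class ConservationError(ErwsimError, RuntimeError):
    """Internal mass-balance trap: a pool was driven negative (a bug, not user error)."""
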