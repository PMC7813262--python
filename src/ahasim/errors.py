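"""Exception hierarchy for the simulator."""


class AhasimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AhasimError):
    """A config file or architecture definition is invalid."""


class IncompatibleGenomesError(AhasimError):
    """Genetic operators applied to genomes built from different architectures."""


class ModeError(AhasimError):
    """An operation was called in an agent tier that does not support it."""


class DeadEndError(AhasimError):
    """No action is available; callers should treat this as forced rest."""
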