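"""Exception hierarchy shared across the pipeline."""


class TernadockError(Exception):
    """Base class for every error raised by this package."""


class PDBFormatError(TernadockError):
    """A PDB record could not be parsed; the message names the line."""


class EmptyStructureError(TernadockError):
    """No ATOM/HETATM records were found where at least one is required."""


class ConsistencyError(TernadockError):
    """A cross-reference (moiety tag, chain id, serial) does not resolve."""


class ConfigurationError(TernadockError):
    """A provider or adapter is requested but not usable as configured."""


class ProviderError(TernadockError):
    """An external score provider ran but its output could not be used."""


class PipelineStageError(TernadockError):
    """A stage of the pipeline emptied the candidate set or cannot proceed."""


class ResidueMappingError(TernadockError):
    """Model and reference structures cannot be put in residue correspondence."""
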