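"""Exception hierarchy."""


class PPIScreenError(Exception):
    """Base class for all package errors."""


class PDBFormatError(PPIScreenError):
    """A coordinate file could not be interpreted (bad record, unknown element)."""


class ConfigurationError(PPIScreenError):
    """Inconsistent or incomplete user configuration (missing chain, bad spec)."""


class ResidueNotFoundError(PPIScreenError, LookupError):
    """A residue identifier does not exist in the complex."""


class ModelingError(PPIScreenError):
    """Training or scoring could not proceed (degenerate labels, empty model)."""
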