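"""Exception hierarchy shared across the pipeline stages."""


class PhytomarkerError(Exception):
    """Base class for all package errors."""


class TableFormatError(PhytomarkerError):
    """A tabular input violates the expected layout (ids, header, dtypes)."""


class TableValidationError(PhytomarkerError):
    """A structurally valid table contains invalid values (negative, missing)."""


class AlignmentError(PhytomarkerError):
    """Two tables cannot be matched on shared sample identifiers."""


class ConfigError(PhytomarkerError):
    """An invalid configuration value or combination."""


class FitError(PhytomarkerError):
    """A numerical fit could not be carried out (singular, degenerate input)."""


class LookupError_(PhytomarkerError):
    """An identifier (assay, compound, fixture name) is unknown."""
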