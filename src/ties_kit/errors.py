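"""Exception hierarchy shared across the toolkit."""


class TiesKitError(Exception):
    """Base class for all toolkit errors."""


class LigandFormatError(TiesKitError):
    """A ligand file could not be parsed, or a mandatory field is missing."""


class MappingStageError(TiesKitError):
    """An atom mapping was passed to a stage it has not been prepared for."""


class SchemaError(TiesKitError):
    """A structured text document violates its declared schema."""


class CoverageError(TiesKitError):
    """Per-window statistics do not cover the full lambda schedule."""
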