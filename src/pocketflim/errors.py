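"""Exception hierarchy shared across the package."""


class PocketFlimError(Exception):
    """Base class for all package-specific errors."""


class StructureFormatError(PocketFlimError):
    """File could not be parsed under the named structure format."""


class EmptyStructureError(PocketFlimError):
    """Parsed structure contains no atoms."""


class SelectionError(PocketFlimError):
    """Ligand/residue selector matched nothing."""


class EmptyPocketError(PocketFlimError):
    """Operation requires a non-empty pocket."""


class DegenerateGeometryError(PocketFlimError):
    """Point set too small or degenerate (collinear/coplanar) for the requested geometry."""


class ConstantInputError(PocketFlimError):
    """Correlation undefined for a constant vector."""


class InsufficientDataError(PocketFlimError):
    """Fewer observations than the statistic requires."""


class CollinearReferencesError(PocketFlimError):
    """Reference phasors are collinear; the unmixing triangle is degenerate."""


class FitError(PocketFlimError):
    """Model fit failed to converge; carries optimizer diagnostics."""


class ConfigError(PocketFlimError):
    """Invalid run configuration."""
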