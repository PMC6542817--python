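"""Exception hierarchy shared across the pipeline."""


class TesselocError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TesselocError):
    """A localization table is malformed (missing columns, bad cells)."""


class GeometryError(TesselocError):
    """Input geometry is degenerate (too few seeds, collinear points, ...)."""


class ConfigError(TesselocError):
    """An analysis parameter is out of its valid range."""


class SimulationError(TesselocError):
    """A simulation request could not be satisfied (e.g. infeasible packing)."""


class RegistrationError(TesselocError):
    """Fiducial-based registration could not be fitted."""
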