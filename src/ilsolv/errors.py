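"""Exception hierarchy shared across the package."""


class IlsolvError(Exception):
    """Base class for all package errors."""


class FormatError(IlsolvError):
    """Malformed input data (trajectory, dump, table)."""


class ConfigError(IlsolvError):
    """Invalid or missing configuration (box, units, settings)."""


class SelectionError(IlsolvError):
    """A site-label or species selection matched nothing or is unknown."""


class UnwrapError(IlsolvError):
    """Frame-to-frame displacement too large to resolve periodic images."""


class DegenerateFrameError(IlsolvError):
    """Local-frame anchors are collinear or coincident."""
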