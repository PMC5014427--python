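"""Exception hierarchy shared across the package."""


class MycomorphError(Exception):
    """Base class for all package-specific errors."""


class NetworkIntegrityError(MycomorphError):
    """A hyphal network violates a structural invariant (cycle, orphan, bad degree)."""


class MorphologyParseError(MycomorphError):
    """A morphology file could not be parsed; the message names the offending record."""


class LineageError(MycomorphError):
    """Two nodes do not lie on a single root-to-tip lineage."""


class DisjointTreesError(LineageError):
    """Two nodes belong to different trees of the forest."""


class NoActiveTipsError(MycomorphError):
    """A mean over active tips was requested but no track is active."""


class UndefinedRatioError(MycomorphError):
    """A ratio with a zero denominator (e.g. no apical branch sites)."""


class DegenerateHistogramError(MycomorphError):
    """An image histogram has a single occupied gray level; no threshold exists."""


class ConfigError(MycomorphError):
    """Invalid or unknown configuration content."""
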