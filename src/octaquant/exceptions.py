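"""Exception hierarchy for octaquant."""


class OctaquantError(Exception):
    """Base class for all octaquant errors."""


class GridMismatchError(OctaquantError):
    """Two rasters that must share a pixel grid do not."""


class GeometryError(OctaquantError):
    """A phantom configuration describes geometrically inconsistent anatomy."""


class LutError(OctaquantError):
    """A color lookup table violates its monotonicity/injectivity contract."""


class DecodeError(OctaquantError):
    """A color map could not be decoded (too many off-path pixels)."""


class RegistrationError(OctaquantError):
    """Control points are insufficient or degenerate for an affine fit."""


class RirtError(OctaquantError):
    """Thickness-ratio computation failed (e.g. too many zero-baseline pixels)."""


class StatsError(OctaquantError):
    """A statistical routine received a degenerate input."""
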