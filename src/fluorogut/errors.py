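"""Exception hierarchy for the fluorogut pipeline.

Every anticipated failure mode maps to a named exception so that callers
(and the CLI) can distinguish, e.g., an occluded probe from a malformed
input file.
"""


class FluorogutError(Exception):
    """Base class for all pipeline errors."""


class EmptyBandError(FluorogutError, ValueError):
    """A spectral band contains no samples of the wavelength grid."""


class LaserNormalizationError(FluorogutError, ValueError):
    """The background-subtracted laser band sum is non-positive.

    In practice this flags an occluded or detached probe: without a valid
    backscattered-laser measurement the fluorescence signal cannot be
    normalised for laser power.
    """


class NoPeakError(FluorogutError, ValueError):
    """No uptake peak is detectable above the baseline / noise floor."""


class DuplicateTimestampError(FluorogutError, ValueError):
    """Two acquisition records share the same session timestamp."""


class SpectrumParseError(FluorogutError, ValueError):
    """A spectrum file is malformed (missing header key, bad grid, ...)."""


class ManifestError(FluorogutError, ValueError):
    """A session manifest is malformed or references missing files."""


class ScenarioError(FluorogutError, ValueError):
    """Unknown synthetic scenario name."""
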