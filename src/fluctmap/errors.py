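"""Exception hierarchy.

``InputError`` maps to CLI exit code 1 (bad inputs, bad config, missing
calibration); anything else escaping a stage maps to exit code 2.
"""


class FluctmapError(Exception):
    """Base class for all package errors."""


class InputError(FluctmapError):
    """Unreadable, malformed or physically uncalibrated input."""


class DegenerateTableError(FluctmapError):
    """Contingency table whose marginals make kappa undefined (pe = 1)."""
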