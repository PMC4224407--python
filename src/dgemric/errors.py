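"""Typed exceptions raised across the pipeline."""


class DgemricError(Exception):
    """Base class for all package errors."""


class ProtocolError(DgemricError):
    """Acquisition protocol is inconsistent (e.g. wrong TI count)."""


class ConfigurationError(DgemricError):
    """Invalid study design or pipeline configuration."""


class CorrectionError(DgemricError):
    """Fat-reference normalization cannot be computed or applied."""


class StateError(DgemricError):
    """Operation called in the wrong state (e.g. factors not filled)."""


class InputError(DgemricError):
    """Shape or value mismatch between user-supplied arrays."""


class FitError(DgemricError):
    """Geometric fit failed (degenerate points, non-elliptical conic)."""


class PairingError(DgemricError):
    """Two maps that must describe the same disc/timepoint do not."""


class IntegrityError(DgemricError):
    """Duplicate or contradictory records in a study table."""


class DesignError(DgemricError):
    """Statistical design is degenerate (aliased factors, too few levels)."""


class GroupingError(DgemricError):
    """Post-hoc grouping invalid (group with fewer than 2 observations)."""


class FormatError(DgemricError):
    """A file on disk does not conform to the documented format."""
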