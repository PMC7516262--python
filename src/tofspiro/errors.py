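"""Exception hierarchy for the depth-spirometry pipeline."""


class TofSpiroError(Exception):
    """Base class for all package-specific errors."""


class SequenceFormatError(TofSpiroError):
    """A depth-sequence directory or frame file is malformed."""


class CohortFormatError(TofSpiroError):
    """A cohort table row violates the record invariants."""


class SubjectAbsentError(TofSpiroError):
    """No foreground pixels survive the background cut: nobody is seated."""


class RoiError(TofSpiroError):
    """The anterior-thorax region could not be extracted."""


class ManeuverError(TofSpiroError):
    """The forced expiratory maneuver is missing, truncated, or flat."""


class CalibrationError(TofSpiroError):
    """The FVC regression cannot be fitted (rank deficiency, too few rows)."""


class EvaluationError(TofSpiroError):
    """Screening evaluation inputs are degenerate or mismatched."""
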