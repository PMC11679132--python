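"""Exception hierarchy.

Every failure a study can produce maps to exactly one machine-readable
reason code so that batch runs can report a failure histogram instead of
aborting. Exceptions that correspond to a per-study failure carry a
``reason`` class attribute; purely programmatic errors (bad configuration,
insufficient data for a statistic) do not.
"""

from __future__ import annotations


class TorsodoseError(Exception):
    """Base class for all package errors."""

    #: per-study failure reason code, or None for programmatic errors
    reason: str | None = None


class InvalidAcquisitionError(TorsodoseError):
    """Dose metadata violates a physical invariant (e.g. CTDIvol <= 0)."""


class InconsistencyError(TorsodoseError):
    """Two inputs disagree (e.g. partition total != acquisition slice count)."""


class ConfigurationError(TorsodoseError):
    """A factor table, region key or config file is malformed."""


class MissingStructureError(TorsodoseError):
    """A required anatomical structure has no voxels in the label volume."""

    reason = "missing_structure"

    def __init__(self, structure: str, detail: str = ""):
        self.structure = structure
        msg = f"required structure {structure!r} absent from label volume"
        if detail:
            msg = f"{msg}: {detail}"
        super().__init__(msg)


class AnatomyInconsistencyError(TorsodoseError):
    """Extracted landmarks violate superior-to-inferior anatomical order."""

    reason = "anatomy_inconsistency"


class MissingDoseReportError(TorsodoseError):
    """No usable CT dose report (DICOM RDSR or JSON sidecar) was found."""

    reason = "missing_dose_report"


class MissingRadionuclideDoseError(TorsodoseError):
    """The PET header lacks an injected-activity value."""

    reason = "missing_radionuclide_dose"


class MissingAgeError(TorsodoseError):
    """Patient age cannot be derived from the PET header."""

    reason = "missing_age"


class UnreadableFileError(TorsodoseError):
    """A discovered input file could not be parsed at all."""

    reason = "unreadable_file"


class PhantomSpecError(TorsodoseError):
    """A synthetic phantom specification is anatomically impossible."""


class InsufficientDataError(TorsodoseError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(TorsodoseError):
    """The statistic is undefined for this input (e.g. zero variance)."""
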