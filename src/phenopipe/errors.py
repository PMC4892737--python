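"""Exception hierarchy for the pipeline.

Every user-facing failure mode gets its own class so callers (and the CLI)
can distinguish bad templates from bad images from empty segmentations.
"""


class PhenopipeError(Exception):
    """Base class for all package errors."""


class BoundsError(PhenopipeError):
    """ROI or coordinate outside the image, or an empty ROI."""


class FilterParseError(PhenopipeError):
    """Malformed color-filter expression; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ArgumentError(PhenopipeError):
    """Operator argument violates its precondition (negative area, even kernel...)."""


class EmptyPlantError(PhenopipeError):
    """No foreground component exceeded the area threshold in contour_cut.

    Carries the list of component areas actually found so the user can pick
    a sensible threshold.
    """

    def __init__(self, message: str, component_areas: list[int]):
        super().__init__(message)
        self.component_areas = component_areas


class EmptyMaskError(PhenopipeError):
    """A descriptor that needs foreground pixels was given an empty mask."""


class TemplateError(PhenopipeError):
    """A workflow/loading/configuration template failed validation.

    ``violations`` is the complete list of problems, each a human-readable
    string naming template, job and field.
    """

    def __init__(self, violations: list[str]):
        super().__init__("template validation failed:\n  " + "\n  ".join(violations))
        self.violations = violations


class SchemaError(PhenopipeError):
    """Metadata CSV or worker database schema mismatch."""


class MissingViewError(PhenopipeError):
    """Composite traits requested but a required camera view is absent."""

    def __init__(self, missing: list[str]):
        super().__init__(f"missing required view(s): {', '.join(missing)}")
        self.missing = missing


class StatsError(PhenopipeError):
    """Degenerate statistical input (zero variance, undersized group...)."""
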