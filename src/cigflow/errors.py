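"""Exception hierarchy shared across the pipeline.

Every stage raises a distinct subclass so the CLI can map failures to
stable exit codes (parse, structuredness, implementability, semantics).
"""

from __future__ import annotations


class CigError(Exception):
    """Base class for all cigflow errors."""


class PatternLookupError(CigError, KeyError):
    """Unknown workflow-pattern id."""

    def __init__(self, pattern_id: int) -> None:
        super().__init__(f"unknown workflow pattern id: {pattern_id!r} (valid ids are 1..43)")
        self.pattern_id = pattern_id


class NotRelevantError(CigError):
    """Pattern exists but was not selected for implementation (suitability 'no')."""

    def __init__(self, pattern_id: int) -> None:
        super().__init__(
            f"pattern #{pattern_id} was not selected for implementation in the "
            f"guideline domain (suitability 'no'); no implementability entry exists"
        )
        self.pattern_id = pattern_id


class BpmnParseError(CigError):
    """Malformed XML or a document violating the interchange dialect."""


class UnsupportedConstructError(BpmnParseError):
    """A BPMN element outside the supported subset; never silently dropped."""

    def __init__(self, tag: str) -> None:
        super().__init__(f"unsupported BPMN construct: <{tag}> is outside the supported subset")
        self.tag = tag


class InvariantError(CigError):
    """A process/model violates its declared invariants; serialization refused."""


class StructurednessError(CigError):
    """Raised by operations that require a structured process.

    Carries the full :class:`~cigflow.bpmn.StructurednessReport`.
    """

    def __init__(self, report) -> None:
        reasons = "; ".join(f"{n}: {r}" for n, r in report.violations)
        super().__init__(f"process is not structured: {reasons}")
        self.report = report


class NotImplementableError(CigError):
    """A detected pattern cannot be implemented in the target language."""

    def __init__(self, pattern_id: int, language: str) -> None:
        super().__init__(
            f"pattern #{pattern_id} is not implementable in {language} "
            f"(implementability matrix label '-')"
        )
        self.pattern_id = pattern_id
        self.language = language


class FixtureSpecError(CigError):
    """Invalid fixture request (non-relevant pattern, bad branch count...)."""


class SemanticsError(CigError):
    """Invalid input to the trace machinery (bad bounds, truncation mismatch...)."""
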