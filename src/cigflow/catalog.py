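"""Workflow control-pattern catalogue.

The 43 control-flow patterns of the Russell / van der Aalst catalogue,
annotated with their suitability for clinical practice guidelines and, for
the relevant subset, with their implementability in the Asbru and PROforma
guideline languages.  The matrices live in a packaged YAML file
(``data/patterns.yaml``) so they can be audited without reading code.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable

import yaml

from .errors import NotRelevantError, PatternLookupError

PATTERN_COUNT = 43

#: Split/join pattern pairs that form one usage scheme; emitters and the
#: recognizer treat each pair as a composite and report the split id first.
COMPOSITE_PAIRS: dict[int, tuple[int, ...]] = {
    2: (2, 3), 3: (2, 3),
    4: (4, 5), 5: (4, 5),
    6: (6, 7), 7: (6, 7),
}


@dataclass(frozen=True)
class PatternDescriptor:
    """One workflow control pattern with its guideline-domain metadata."""

    id: int
    name: str
    suitability: str          # "yes" | "unknown" | "no"
    suitability_note: str
    relevant: bool            # suitability in {yes, unknown}


@dataclass(frozen=True)
class ImplementabilityEntry:
    """One cell of the implementability matrix."""

    pattern_id: int
    language: str             # "asbru" | "proforma"
    label: str                # "direct" | "workaround" | "not_implementable"


class Catalog:
    """In-memory catalogue; normally built once from the packaged data file."""

    def __init__(
        self,
        patterns: Iterable[PatternDescriptor],
        implementability: Iterable[ImplementabilityEntry] = (),
    ) -> None:
        self._patterns = {p.id: p for p in patterns}
        self._impl = {(e.pattern_id, e.language): e for e in implementability}

    @classmethod
    def load(cls) -> "Catalog":
        raw = yaml.safe_load(
            resources.files("cigflow.data").joinpath("patterns.yaml").read_text("utf-8")
        )
        patterns = [
            PatternDescriptor(
                id=row["id"],
                name=row["name"],
                suitability=row["suitability"],
                suitability_note=row["note"],
                relevant=row["suitability"] in ("yes", "unknown"),
            )
            for row in raw["patterns"]
        ]
        impl = [
            ImplementabilityEntry(row["id"], lang, row[lang])
            for row in raw["implementability"]
            for lang in ("asbru", "proforma")
        ]
        cat = cls(patterns, impl)
        cat._check()
        return cat

    def _check(self) -> None:
        ids = sorted(self._patterns)
        if ids != list(range(1, PATTERN_COUNT + 1)):
            raise ValueError("catalogue must cover pattern ids 1..43 exactly once")
        for p in self._patterns.values():
            if p.suitability == "no" and not p.suitability_note:
                raise ValueError(f"pattern #{p.id} dismissed without an explanation")
        for (pid, _), entry in self._impl.items():
            if not self._patterns[pid].relevant:
                raise ValueError(f"implementability entry for non-relevant pattern #{pid}")
            if entry.label not in ("direct", "workaround", "not_implementable"):
                raise ValueError(f"bad implementability label {entry.label!r}")

    # -- operations -------------------------------------------------------

    def get_pattern(self, pattern_id: int) -> PatternDescriptor:
        try:
            return self._patterns[pattern_id]
        except KeyError:
            raise PatternLookupError(pattern_id) from None

    def relevant_patterns(self) -> list[PatternDescriptor]:
        """Patterns selected for the guideline domain, in ascending id order."""
        return [p for _, p in sorted(self._patterns.items()) if p.relevant]

    def suitability_percentage(self) -> int:
        """Share of the catalogue needed to describe guidelines, as a rounded percent."""
        total = len(self._patterns)
        return round(100 * len(self.relevant_patterns()) / total)

    def implementability(self, pattern_id: int, language: str) -> ImplementabilityEntry:
        if language not in ("asbru", "proforma"):
            raise ValueError(f"unknown target language {language!r}")
        descriptor = self.get_pattern(pattern_id)
        if not descriptor.relevant:
            raise NotRelevantError(pattern_id)
        return self._impl[(pattern_id, language)]

    def not_implementable(self, language: str) -> list[int]:
        """Pattern ids whose cell for ``language`` is '-', ascending."""
        return sorted(
            pid for (pid, lang), e in self._impl.items()
            if lang == language and e.label == "not_implementable"
        )

    def workarounds(self, language: str) -> list[int]:
        """Pattern ids whose cell for ``language`` is '+/-', ascending."""
        return sorted(
            pid for (pid, lang), e in self._impl.items()
            if lang == language and e.label == "workaround"
        )


@lru_cache(maxsize=1)
def default_catalog() -> Catalog:
    return Catalog.load()


def get_pattern(pattern_id: int) -> PatternDescriptor:
    return default_catalog().get_pattern(pattern_id)


def relevant_patterns() -> list[PatternDescriptor]:
    return default_catalog().relevant_patterns()


def suitability_percentage() -> int:
    return default_catalog().suitability_percentage()


def implementability(pattern_id: int, language: str) -> ImplementabilityEntry:
    return default_catalog().implementability(pattern_id, language)


def composite_ids(pattern_id: int) -> tuple[int, ...]:
    """Ids jointly realized by one region (e.g. XOR split + XOR join)."""
    return COMPOSITE_PAIRS.get(pattern_id, (pattern_id,))
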