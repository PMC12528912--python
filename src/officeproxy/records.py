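"""Domain types shared across the pipeline.

The pipeline turns three inputs — an occupation classification (titles with
4-digit codes), a translation key (code -> collar category), and a file of
free-text questionnaire responses — into an office-worker proxy (Yes / No /
Unverified) per response.  The types here are the rows of those tables plus
the small enums the collar logic speaks in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: Placeholder used by classification rows that lack a specific 4-digit code.
PLACEHOLDER_CODE = "xxxx"
#: Sentinel assigned to placeholder rows that cannot be resolved; always
#: categorized as unknown.  Stored without a thousands separator.
UNKNOWN_CODE = "10000"


class Collar(str, Enum):
    """Collar category of a single occupation code.

    ``MANAGER`` exists only at the translation-key level: wherever the
    office-worker proxy is concerned, managers count as white-collar.
    """

    MANAGER = "manager"
    WHITE = "white"
    BLUE = "blue"
    UNKNOWN = "unknown"


class Category(str, Enum):
    """Collar category of a collapsed occupation title (lookup row)."""

    WHITE = "White-collar"
    BLUE = "Blue-collar"
    UNVERIFIED = "Unverified"


class OfficeWorker(str, Enum):
    """The office-worker proxy variable."""

    YES = "Yes"
    NO = "No"
    UNVERIFIED = "Unverified"


#: Category <-> proxy are locked together one-to-one.
CATEGORY_TO_PROXY = {
    Category.WHITE: OfficeWorker.YES,
    Category.BLUE: OfficeWorker.NO,
    Category.UNVERIFIED: OfficeWorker.UNVERIFIED,
}
PROXY_TO_CATEGORY = {v: k for k, v in CATEGORY_TO_PROXY.items()}


@dataclass(frozen=True)
class ResponseRecord:
    """One questionnaire row: an opaque id plus a free-text occupation.

    ``occupation_raw`` is ``None`` when the cell was empty (missing value);
    ``occupation_eng`` is an optional translation column the pipeline ignores.
    """

    id: str
    occupation_raw: Optional[str]
    occupation_eng: Optional[str] = None


@dataclass(frozen=True)
class ClassificationEntry:
    """One raw classification row.

    ``code`` is a 4-digit string, the placeholder ``"xxxx"`` or the sentinel
    ``"10000"``.  ``reference_title`` cross-references another occupation
    title and is only meaningful on placeholder rows.
    """

    title: str
    code: str
    reference_title: Optional[str] = None


@dataclass(frozen=True)
class CodeCounts:
    """Per-title tally of collar categories among contributing codes.

    Manager occurrences are folded into ``n_white`` before any majority
    voting; ``n_manager`` is retained separately for reporting only.
    """

    n_white: int = 0
    n_blue: int = 0
    n_unknown: int = 0
    n_manager: int = 0  # informational; already included in n_white

    @property
    def n_codes(self) -> int:
        return self.n_white + self.n_blue + self.n_unknown


class MajorityOutcome(str, Enum):
    """Result of the majority vote over a title's code categories."""

    WHITE = "white"
    BLUE = "blue"
    UNKNOWN = "unknown"
    TIED = "tied"


@dataclass(frozen=True)
class LookupEntry:
    """One reduced, collapsed occupation title of the lookup table.

    ``normalized_title`` is always the normalization of ``title`` (derived,
    never stored on disk).  ``proportion_white`` is ``None`` for supplemental
    titles that carry no classification codes (``from_standard=False``).
    """

    title: str
    normalized_title: str
    from_standard: bool
    n_codes: int
    proportion_white: Optional[float]
    category: Category
    office_worker: OfficeWorker
    counts: Optional[CodeCounts] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if CATEGORY_TO_PROXY[self.category] is not self.office_worker:
            raise ValueError(
                f"inconsistent lookup entry {self.title!r}: category "
                f"{self.category.value} with proxy {self.office_worker.value}"
            )
        if self.proportion_white is not None and not 0.0 <= self.proportion_white <= 1.0:
            raise ValueError(
                f"proportion_white out of [0, 1] for {self.title!r}: "
                f"{self.proportion_white}"
            )
        if self.from_standard and self.n_codes < 1:
            raise ValueError(f"standard-derived entry {self.title!r} has no codes")


@dataclass(frozen=True)
class MatchResult:
    """One response joined to its nearest lookup title.

    ``office_worker`` is present exactly when ``distance == 0`` (a perfect
    match); imperfect matches keep their best candidate and distance to
    support manual review but are never auto-assigned.
    """

    id: str
    occupation_raw: str
    normalized: str
    best_title: str
    distance: float
    office_worker: Optional[OfficeWorker] = None

    def __post_init__(self) -> None:
        if (self.distance == 0.0) != (self.office_worker is not None):
            raise ValueError(
                f"proxy must be present iff distance is 0 (id={self.id!r}, "
                f"distance={self.distance})"
            )


class TranslationKey:
    """Mapping from 4-digit occupation codes to collar categories.

    The key may be given at prefix granularity (e.g. ``"1" -> manager``);
    lookup uses the longest matching prefix.  Codes with no matching entry
    resolve to ``None`` — the caller decides how to warn and fall back.
    """

    def __init__(self, entries: dict[str, Collar]):
        for prefix, collar in entries.items():
            if not prefix.isdigit() or not 1 <= len(prefix) <= 4:
                raise ValueError(f"bad code or prefix in translation key: {prefix!r}")
            if not isinstance(collar, Collar):
                raise ValueError(f"bad category for prefix {prefix!r}: {collar!r}")
        self._entries = dict(entries)

    def lookup(self, code: str) -> Optional[Collar]:
        """Longest-prefix collar lookup; ``None`` when no prefix matches."""
        for length in range(min(len(code), 4), 0, -1):
            collar = self._entries.get(code[:length])
            if collar is not None:
                return collar
        return None

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TranslationKey) and self._entries == other._entries
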