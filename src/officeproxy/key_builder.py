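"""Build the reduced, collapsed, categorized occupation lookup.

A raw occupation classification lists full titles with 4-digit codes, e.g.
"Civilingenjör, gruvteknik och metallurgi" under code 2146.  Questionnaire
respondents answer far more coarsely ("Civilingenjör"), so the lookup is
built in four steps:

1. resolve placeholder codes ("xxxx") via cross-references;
2. reduce each title to its first part (text before the first comma);
3. collapse rows with the same reduced title, tallying the collar category
   of each contributing code through the translation key;
4. assign each collapsed title a category by majority vote and from it the
   office-worker proxy: white-collar -> Yes, blue-collar -> No, unknown or
   tied -> Unverified.

Armed-forces codes (leading 0) are categorized as unknown regardless of the
translation key: the share of office work in that group cannot be assessed.
Managers count as white-collar throughout.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional, Sequence

from .normalize import normalize_text
from .records import (
    CATEGORY_TO_PROXY,
    PLACEHOLDER_CODE,
    PROXY_TO_CATEGORY,
    UNKNOWN_CODE,
    Category,
    ClassificationEntry,
    CodeCounts,
    Collar,
    LookupEntry,
    MajorityOutcome,
    OfficeWorker,
    TranslationKey,
)

logger = logging.getLogger(__name__)

#: Default delimiters at which a full classification title is cut down to
#: the coarse occupation a respondent would actually write.
DEFAULT_REDUCTION_DELIMITERS: tuple[str, ...] = (",",)


def resolve_placeholder_codes(
    entries: Sequence[ClassificationEntry],
) -> list[ClassificationEntry]:
    """Replace every placeholder code with a concrete code.

    Rules, applied per placeholder row:

    * the cross-referenced title carries a single distinct code -> use it;
    * several distinct codes sharing leading digits -> keep the common
      prefix, zero-fill the rest;
    * the first digit differs -> most frequent first digit (over code
      occurrences; ties broken toward the smaller digit) followed by "000";
    * no reference, or a reference naming no coded title -> the sentinel
      "10000" (categorized unknown downstream), with a warning.

    Non-placeholder rows pass through unchanged; order is preserved.
    """
    coded_by_title: dict[str, list[str]] = {}
    for entry in entries:
        if entry.code != PLACEHOLDER_CODE:
            coded_by_title.setdefault(normalize_text(entry.title), []).append(
                entry.code
            )

    resolved: list[ClassificationEntry] = []
    for entry in entries:
        if entry.code != PLACEHOLDER_CODE:
            resolved.append(entry)
            continue
        codes: list[str] = []
        if entry.reference_title is not None:
            codes = [
                c
                for c in coded_by_title.get(normalize_text(entry.reference_title), [])
                if c != UNKNOWN_CODE
            ]
            if not codes:
                logger.warning(
                    "placeholder %r references %r which has no coded entry; "
                    "falling back to %s",
                    entry.title,
                    entry.reference_title,
                    UNKNOWN_CODE,
                )
        resolved.append(
            ClassificationEntry(
                title=entry.title,
                code=_resolve_codes(codes),
                reference_title=entry.reference_title,
            )
        )
    return resolved


def _resolve_codes(codes: list[str]) -> str:
    if not codes:
        return UNKNOWN_CODE
    distinct = sorted(set(codes))
    if len(distinct) == 1:
        return distinct[0]
    first_digits = {c[0] for c in distinct}
    if len(first_digits) == 1:
        prefix = _common_prefix(distinct)
        return prefix + "0" * (4 - len(prefix))
    counts = Counter(c[0] for c in codes)
    top = max(counts.values())
    digit = min(d for d, n in counts.items() if n == top)
    return digit + "000"


def _common_prefix(codes: list[str]) -> str:
    prefix = codes[0]
    for code in codes[1:]:
        while not code.startswith(prefix):
            prefix = prefix[:-1]
    return prefix


def categorize_code(code: str, key: TranslationKey) -> Collar:
    """Collar category of one resolved code.

    The armed-forces override comes first: codes starting with "0" are
    unknown even though the translation key files them as white-collar.
    The "10000" sentinel is unknown by construction.  Managers are folded
    into white-collar here; callers wanting the manager tally must consult
    the key directly.
    """
    if code == UNKNOWN_CODE:
        return Collar.UNKNOWN
    if code.startswith("0"):
        return Collar.UNKNOWN
    collar = key.lookup(code)
    if collar is None:
        logger.warning("code %s has no translation-key entry; categorized unknown", code)
        return Collar.UNKNOWN
    if collar is Collar.MANAGER:
        return Collar.WHITE
    return collar


def reduce_title(
    title: str, delimiters: Sequence[str] = DEFAULT_REDUCTION_DELIMITERS
) -> str:
    """Extract the first part of a full classification title.

    Cuts at the earliest occurrence of any delimiter (default: the first
    comma) and trims whitespace.  A title without delimiters, or one whose
    reduction would be empty, is kept whole (the latter with a warning).
    """
    cut = min((i for i in (title.find(d) for d in delimiters) if i >= 0), default=-1)
    if cut < 0:
        return title.strip()
    head = title[:cut].strip()
    if not head:
        logger.warning("reduction of %r would be empty; keeping full title", title)
        return title
    return head


def majority_category(counts: CodeCounts) -> MajorityOutcome:
    """Majority vote over a title's collar tallies.

    A unique strict plurality wins.  White and blue tied at the maximum is
    a tie (likewise all three equal); a category tied with unknown alone at
    the maximum wins over unknown.
    """
    w, b, u = counts.n_white, counts.n_blue, counts.n_unknown
    if w == 0 and b == 0 and u == 0:
        raise ValueError("majority vote over empty code counts")
    top = max(w, b, u)
    if w == top and b == top:
        return MajorityOutcome.TIED
    if w == top:
        return MajorityOutcome.WHITE
    if b == top:
        return MajorityOutcome.BLUE
    return MajorityOutcome.UNKNOWN


def proportion_white(counts: CodeCounts) -> float:
    """Share of white-collar codes among all codes of a title."""
    total = counts.n_codes
    if total == 0:
        raise ValueError("proportion over empty code counts")
    return counts.n_white / total


def assign_proxy(outcome: MajorityOutcome) -> OfficeWorker:
    """Office-worker proxy from the majority outcome."""
    if outcome is MajorityOutcome.WHITE:
        return OfficeWorker.YES
    if outcome is MajorityOutcome.BLUE:
        return OfficeWorker.NO
    return OfficeWorker.UNVERIFIED


def _category_for(outcome: MajorityOutcome) -> Category:
    return PROXY_TO_CATEGORY[assign_proxy(outcome)]


def collapse(
    entries: Sequence[ClassificationEntry],
    key: TranslationKey,
    delimiters: Sequence[str] = DEFAULT_REDUCTION_DELIMITERS,
) -> list[LookupEntry]:
    """Collapse resolved classification rows into lookup entries.

    Rows are grouped on the normalized reduced title, so case and
    punctuation variants of the same occupation merge; the displayed title
    is the first-seen original spelling.  Output is sorted by normalized
    title and therefore independent of input row order.

    Precondition: placeholder codes must already be resolved.
    """
    groups: dict[str, tuple[str, list[str]]] = {}
    for entry in entries:
        if entry.code == PLACEHOLDER_CODE:
            raise ValueError(
                f"unresolved placeholder code on {entry.title!r}; run "
                "resolve_placeholder_codes first"
            )
        reduced = reduce_title(entry.title, delimiters)
        norm = normalize_text(reduced)
        if norm not in groups:
            groups[norm] = (reduced, [])
        groups[norm][1].append(entry.code)

    result: list[LookupEntry] = []
    for norm in sorted(groups):
        display, codes = groups[norm]
        n_white = n_blue = n_unknown = n_manager = 0
        for code in codes:
            collar = categorize_code(code, key)
            if collar is Collar.WHITE:
                n_white += 1
                if key.lookup(code) is Collar.MANAGER:
                    n_manager += 1
            elif collar is Collar.BLUE:
                n_blue += 1
            else:
                n_unknown += 1
        counts = CodeCounts(
            n_white=n_white, n_blue=n_blue, n_unknown=n_unknown, n_manager=n_manager
        )
        outcome = majority_category(counts)
        result.append(
            LookupEntry(
                title=display,
                normalized_title=norm,
                from_standard=True,
                n_codes=counts.n_codes,
                proportion_white=proportion_white(counts),
                category=_category_for(outcome),
                office_worker=assign_proxy(outcome),
                counts=counts,
            )
        )
    return result


def build_lookup(
    entries: Sequence[ClassificationEntry],
    key: TranslationKey,
    delimiters: Sequence[str] = DEFAULT_REDUCTION_DELIMITERS,
) -> list[LookupEntry]:
    """Full lookup construction: resolve placeholders, then collapse."""
    return collapse(resolve_placeholder_codes(entries), key, delimiters)


def merge_supplemental(
    lookup: Sequence[LookupEntry],
    extra: Iterable[tuple[str, OfficeWorker]],
) -> list[LookupEntry]:
    """Append expert-labelled titles that did not come from the standard.

    Supplemental titles carry no classification codes: ``n_codes`` is 0 and
    the white-collar proportion is missing.  A supplemental title whose
    normalized form collides with an existing entry (or another supplemental
    title) is an error listing all offenders.
    """
    seen = {e.normalized_title for e in lookup}
    merged = list(lookup)
    duplicates: list[str] = []
    for title, proxy in extra:
        proxy = OfficeWorker(proxy)
        norm = normalize_text(title)
        if norm in seen:
            duplicates.append(title)
            continue
        seen.add(norm)
        merged.append(
            LookupEntry(
                title=title,
                normalized_title=norm,
                from_standard=False,
                n_codes=0,
                proportion_white=None,
                category=PROXY_TO_CATEGORY[proxy],
                office_worker=proxy,
            )
        )
    if duplicates:
        raise ValueError(
            "supplemental titles collide with existing lookup entries: "
            + ", ".join(repr(t) for t in duplicates)
        )
    return merged
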