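"""Clean responses, fuzzy-join them to the lookup, and assign the proxy.

Responses with a missing occupation text are dropped (and counted); the
rest are normalized and joined to the lookup title with the smallest Jaro
distance.  Only perfect matches (distance exactly 0, i.e. the normalized
strings are identical) receive the office-worker proxy; imperfect matches
keep their best candidate and distance for manual review.

The join first tries an exact hash lookup on normalized strings and only
scans all titles for responses without an exact hit; results are identical
to the naive all-pairs scan because distance 0 occurs exactly at string
equality and normalized lookup titles are unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .normalize import normalize_text
from .records import LookupEntry, MatchResult, OfficeWorker, ResponseRecord
from .stringdist import jaro_distance


def clean_responses(
    records: Sequence[ResponseRecord],
) -> tuple[list[ResponseRecord], int]:
    """Drop records with missing occupation text; count the drops.

    A text that is ``None`` or only whitespace is missing.  The input
    sequence is left untouched; a new list is returned.
    """
    kept = [
        r
        for r in records
        if r.occupation_raw is not None and r.occupation_raw.strip() != ""
    ]
    return kept, len(records) - len(kept)


def match_responses(
    records: Sequence[ResponseRecord],
    lookup: Sequence[LookupEntry],
) -> tuple[list[MatchResult], list[MatchResult]]:
    """Join each cleaned response to its minimum-distance lookup title.

    Returns ``(perfect, imperfect)``: records at distance 0 with the proxy
    copied from the matched entry, and all others without a proxy.  Every
    record lands in exactly one list, in input order.  Ties among entries at
    equal minimal positive distance are broken by lexicographic order of the
    normalized title.

    Raises on an empty lookup or on duplicate normalized lookup titles
    (uniqueness is what makes perfect matches unambiguous).
    """
    if not lookup:
        raise ValueError("lookup is empty; nothing to match against")
    by_norm: dict[str, LookupEntry] = {}
    for entry in lookup:
        if entry.normalized_title in by_norm:
            raise ValueError(
                f"duplicate normalized lookup title {entry.normalized_title!r}"
            )
        by_norm[entry.normalized_title] = entry
    scan_order = sorted(by_norm)  # lexicographic tie-break for free

    perfect: list[MatchResult] = []
    imperfect: list[MatchResult] = []
    for record in records:
        raw = record.occupation_raw or ""
        norm = normalize_text(raw)
        hit = by_norm.get(norm)
        if hit is not None:
            perfect.append(
                MatchResult(
                    id=record.id,
                    occupation_raw=raw,
                    normalized=norm,
                    best_title=hit.title,
                    distance=0.0,
                    office_worker=hit.office_worker,
                )
            )
            continue
        best_norm, best_dist = None, 2.0
        for cand in scan_order:
            d = jaro_distance(norm, cand)
            if d < best_dist:
                best_norm, best_dist = cand, d
        imperfect.append(
            MatchResult(
                id=record.id,
                occupation_raw=raw,
                normalized=norm,
                best_title=by_norm[best_norm].title,
                distance=best_dist,
                office_worker=None,
            )
        )
    return perfect, imperfect


@dataclass(frozen=True)
class MatchSummary:
    """Counts of the matching run, as reported to the user."""

    n_input: int
    n_missing_dropped: int
    n_matched: int
    n_unmatched: int
    n_yes: int
    n_no: int
    n_unverified: int

    @property
    def match_rate(self) -> Optional[float]:
        """Matched share of non-missing responses; ``None`` if none exist."""
        denom = self.n_matched + self.n_unmatched
        return self.n_matched / denom if denom else None

    def render(self) -> str:
        rate = self.match_rate
        rate_str = f"{round(rate * 100)} %" if rate is not None else "n/a"
        return "\n".join(
            [
                f"responses read:        {self.n_input}",
                f"missing, dropped:      {self.n_missing_dropped}",
                f"perfect matches:       {self.n_matched}",
                f"unmatched:             {self.n_unmatched}",
                f"match rate:            {rate_str}",
                f"office worker Yes:     {self.n_yes}",
                f"office worker No:      {self.n_no}",
                f"office worker Unverified: {self.n_unverified}",
            ]
        )


def summarize(
    perfect: Sequence[MatchResult],
    imperfect: Sequence[MatchResult],
    n_dropped: int,
) -> MatchSummary:
    """Tally a matching run into a :class:`MatchSummary`."""
    tally = {OfficeWorker.YES: 0, OfficeWorker.NO: 0, OfficeWorker.UNVERIFIED: 0}
    for result in perfect:
        tally[result.office_worker] += 1
    return MatchSummary(
        n_input=len(perfect) + len(imperfect) + n_dropped,
        n_missing_dropped=n_dropped,
        n_matched=len(perfect),
        n_unmatched=len(imperfect),
        n_yes=tally[OfficeWorker.YES],
        n_no=tally[OfficeWorker.NO],
        n_unverified=tally[OfficeWorker.UNVERIFIED],
    )
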