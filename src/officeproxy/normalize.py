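"""Text canonicalization applied before any string matching.

Free-text occupation responses and lookup titles are compared only after
lowercasing and stripping every character that is not a letter.  "Letter"
means the Unicode letter predicate, so Swedish å/ä/ö survive while spaces,
punctuation, digits and other symbols are removed.  Matching then reduces to
exact string equality (Jaro distance 0) for responses that differ from a
title only in case, spacing or punctuation.
"""

from __future__ import annotations


def normalize_text(raw: str, *, keep_digits: bool = False) -> str:
    """Lowercase ``raw`` and drop every non-letter character.

    Uses Unicode case folding (not ASCII lowercasing) so non-ASCII letters
    fold correctly.  With ``keep_digits=True`` decimal digits are retained;
    the default strips them, treating digits as symbols.

    The operation is total: empty input yields the empty string, which
    callers treat as a missing value.  It is idempotent and deterministic.
    """
    folded = raw.casefold()
    return "".join(
        ch for ch in folded if ch.isalpha() or (keep_digits and ch.isdigit())
    )
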