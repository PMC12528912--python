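"""Jaro similarity and distance, implemented from the definition.

For strings ``a`` and ``b``, characters count as matching when they are
equal and no further apart than ``floor(max(|a|, |b|) / 2) - 1`` positions.
With ``m`` matching characters and ``t`` the number of transpositions (half
the count of positions where the two matched-character sequences disagree),

    sim(a, b) = (m/|a| + m/|b| + (m - t)/m) / 3

and the distance is ``1 - sim``.  The distance is 0 exactly for identical
strings, which is what the perfect-match split of the matcher relies on.

Convention for empty strings: both empty -> similarity 1; exactly one
empty -> similarity 0.  Empty responses never reach matching in practice.
"""

from __future__ import annotations


def jaro_similarity(a: str, b: str) -> float:
    """Jaro similarity in [0, 1]; symmetric; 1 iff the strings are equal."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0

    window = max(max(la, lb) // 2 - 1, 0)
    a_matched = [False] * la
    b_matched = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_matched[j] and b[j] == ca:
                a_matched[i] = True
                b_matched[j] = True
                m += 1
                break
    if m == 0:
        return 0.0

    # transpositions: compare the matched characters in their original order
    b_seq = [cb for j, cb in enumerate(b) if b_matched[j]]
    half_transposed = sum(
        1
        for ca, cb in zip((c for i, c in enumerate(a) if a_matched[i]), b_seq)
        if ca != cb
    )
    t = half_transposed // 2
    return (m / la + m / lb + (m - t) / m) / 3.0


def jaro_distance(a: str, b: str) -> float:
    """``1 - jaro_similarity``; 0 exactly when the strings are identical."""
    if a == b:
        return 0.0
    return 1.0 - jaro_similarity(a, b)
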