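# Methods

## The procedure

The pipeline assigns an office-worker proxy (Yes / No / Unverified) to
free-text occupation responses in two stages.

**Stage 1 — lookup construction.** The input is an occupation
classification (full titles with 4-digit codes; some rows carry the
placeholder code `xxxx` and a cross-reference instead) and a translation
key mapping codes, possibly at prefix granularity, to manager /
white-collar / blue-collar. Construction proceeds:

1. *Placeholder resolution.* A placeholder row whose reference names a
   title with one distinct code takes that code. If the referred title
   occurs with several codes sharing leading digits, the common prefix is
   kept and the remainder zero-filled (`{3151, 3155}` → `3150`). If even
   the first digit differs, the most frequent first digit (counted over
   code occurrences) is kept and followed by `000`; an equal-frequency tie
   is broken toward the smaller digit — the source procedure does not
   specify this case, and a deterministic rule keeps rebuilds
   reproducible. A placeholder without a usable reference becomes the
   sentinel `10000`, categorized unknown.
2. *Categorization.* Each code maps through the key, with two overrides:
   armed-forces codes (leading 0) are unknown regardless of the key,
   because the share of office work in that group cannot be assessed, and
   managers count as white-collar wherever the proxy is concerned. Codes
   absent from the key are unknown, with a warning.
3. *Reduction and collapse.* Titles are cut at the first reduction
   delimiter (default: the first comma; configurable, since classification
   exports differ in punctuation) and trimmed; a reduction that would be
   empty keeps the whole title with a warning. Rows are grouped on the
   *normalized* reduced title, so case/punctuation variants merge; the
   displayed spelling is the first seen, and output is sorted by
   normalized title, making the result independent of input row order.
4. *Majority vote.* Per group, the collar tallies (white including
   managers, blue, unknown) are compared: a unique strict plurality wins;
   white tied with blue at the maximum is a tie, as is a three-way tie;
   white or blue tied only with unknown beats unknown. White → proxy Yes,
   blue → No, unknown or tied → Unverified. The tally happens after
   managers are folded into white; folding first is a choice (the
   alternative ordering is not described in the source procedure), and it
   is the one consistent with managers being office workers by definition.
   The recorded white-collar proportion is `n_white / n_codes` with
   unknown-coded rows included in the denominator ("all codes").

Expert-labelled supplemental titles can be merged afterwards; they carry
no codes (`n_codes = 0`, proportion missing) and must not collide with an
existing normalized title.

**Stage 2 — matching.** Responses with an empty occupation cell are
dropped and counted. The rest are normalized — Unicode case folding, then
removal of every non-letter character (digits included; a `keep_digits`
switch exists because classification exports occasionally carry numerals,
but occupation text is alphabetic) — and joined to the lookup title at
minimal Jaro distance. Only distance exactly 0 assigns the proxy; since
normalized lookup titles are unique (enforced at match time), a perfect
match is unambiguous. Imperfect matches keep their best candidate and
distance for manual review; no automatic assignment happens below any
nonzero threshold. The join short-circuits through a hash of normalized
titles and scans only on a miss, which is indistinguishable from the
all-pairs scan because distance 0 occurs exactly at string equality.

## Jaro distance

Implemented from the definition in double precision: matches are equal
characters within ⌊max(|a|,|b|)/2⌋ − 1 positions, assigned greedily
left-to-right; transpositions are half the disagreements between the two
matched sequences. Conventions: two empty strings are similarity 1,
exactly one empty is 0 (empty responses never reach matching). Plain Jaro
is used, not Jaro–Winkler: no prefix bonus. The perfect-match split
compares `distance == 0` exactly; identical strings return exactly 0.0 by
construction, so no tolerance is involved. The test suite checks the
implementation against an independent brute-force evaluation of the
definition on randomized short strings (agreement to 1e-12).

## File formats

Canonical interchange is semicolon-separated CSV, UTF-8, header row
first, empty cell = missing, numbers with a decimal point (a
`decimal_comma` flag accepts comma-decimal files on read; default off).
`.xlsx` is accepted read-only. All column names are configurable, with
defaults matching the published datasets (`ID` / `Occupation_swe`;
`Occupation title`, `From SSYK12`, `#SSYK12`, `Proportion white collar`,
`Category`, `Office worker`). Writers and readers round-trip exactly;
floats are written with `repr`, which round-trips in IEEE double.

## Synthetic data

The generator emulates the *structure* of the real inputs: 4-digit codes
whose first digit fixes the collar band (1 manager, 2–4 white, 5–9 blue,
0 armed forces), multi-code titles written as "Stem, specialization" so
collapsing is exercised, placeholder rows cycling through all four
resolution rules, and a Swedish-like vocabulary with å/ä/ö so non-ASCII
folding is exercised. Responses are, with configurable probabilities,
exact titles, case/space/symbol variants (perfect matches by
construction), single-character typos applied to the normalized form and
regenerated on collision with any lookup title (imperfect by
construction), or missing cells. Ground truth is recorded per title and
per response as the fixture is built.

Defaults are fixed study conditions: 200 title concepts with 1–3 codes
each; collar mix (manager 0.08, white 0.46, blue 0.43, armed forces 0.01,
placeholder 0.02), approximating the published lookup's Yes/No/Unverified
balance of 3550/2968/83; 700 responses (the size of the published example
response file) mixing exact 0.45, variant 0.21, typo 0.30, missing 0.04,
which yields a match rate near the 69 % reported for comparable pilot
data. These sizes keep the full suite and the acceptance run to seconds
while leaving every code path exercised.

What the generator does **not** emulate: the real title- and
code-frequency distribution, multi-word free-text answers ("works at a
bank"), spelling errors that happen to form another valid title, and
language mixing. Passing tests therefore demonstrate that the mechanism
is correct — normalization-invariant responses always match and recover
their label; perturbed responses never receive a proxy — not that any
particular match rate will be achieved on real questionnaire data.

## Numerical and degenerate-input choices

- Majority votes and perfect-match splits are integer/equality logic; the
  only floating arithmetic is the Jaro formula and the white proportion.
- Empty code tallies (no contributing rows) raise rather than default.
- Ties among lookup candidates at equal minimal *positive* distance are
  broken by lexicographic order of the normalized title; this affects
  only which near-miss candidate is reported.
- Duplicate normalized lookup titles are rejected at match time rather
  than silently tie-broken.
- A response that normalizes to the empty string (e.g. "???") is not
  dropped — dropping is decided on the raw text — and lands among the
  imperfect matches at distance 1.

## Limitations

- The proxy inherits the collar approximation: white-collar occupations
  with little office work (nursing, teaching) are still Yes.
- Only perfect matches are assigned, so recall on real free text depends
  entirely on respondents writing a reduced title verbatim; the unmatched
  file plus `merge_supplemental` support the manual-review loop that
  raises coverage.
- The reduction rule (first comma) is a configurable guess at the exact
  editorial convention of any given classification export; rebuilding
  against a published lookup (see `scripts/reproduce_published.py`) is the
  way to validate it for a new source.
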