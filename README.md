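# officeproxy

Epidemiological questionnaires often ask about occupation as an open-ended
question ("What is your occupation?") but rarely ask whether the respondent
works in an office. When office workers are the study population — for
example in research on sedentary behaviour — the free-text occupation must
be turned into an office-worker indicator after the fact. `officeproxy`
implements a semi-automated pipeline for doing that in Swedish data:

1. **Build a lookup** from an occupation classification standard
   (titles with 4-digit codes, such as SSYK 2012, the Swedish adaptation of
   ISCO-08) and a translation key that files each code as *manager*,
   *white-collar* (tjänsteman) or *blue-collar* (arbetare). Full titles are
   reduced to their first part ("Civilingenjör, gruvteknik och metallurgi" →
   "Civilingenjör"), rows with the same reduced title are collapsed, and
   each reduced title gets a collar category by **majority vote** over its
   contributing codes. White-collar (managers included) maps to the
   office-worker proxy **Yes**, blue-collar to **No**, and unknown or tied
   titles to **Unverified**. Armed-forces codes (leading 0) are always
   treated as unknown, and placeholder codes ("xxxx") are resolved through
   their cross-references.
2. **Match responses**: each free-text answer is normalized (lowercased,
   all non-letter characters stripped) and joined to the lookup title with
   the smallest **Jaro distance**,

   d(a, b) = 1 − (m/|a| + m/|b| + (m − t)/m) / 3,

   where *m* counts characters matching within a window of
   ⌊max(|a|,|b|)/2⌋ − 1 positions and *t* the transpositions among them.
   Only perfect matches (d = 0, i.e. identical normalized strings) receive
   the proxy; near misses keep their best candidate and distance for manual
   review.

A seeded synthetic-data module generates toy classifications, translation
keys and response files with known ground truth, so the whole pipeline is
testable without downloading the real standard.

## Worked example

Simulate a small world, build its lookup, and match the responses:

```sh
officeproxy simulate --out-dir fx --seed 1
officeproxy build-key --classification fx/classification.csv \
    --key fx/translation_key.csv --out fx/lookup.csv
officeproxy match --lookup fx/lookup.csv --responses fx/responses.csv \
    --matched-out fx/matched.csv --unmatched-out fx/unmatched.csv
```

The match step prints:

```
responses read:        700
missing, dropped:      25
perfect matches:       458
unmatched:             217
match rate:            68 %
office worker Yes:     221
office worker No:      223
office worker Unverified: 14
```

700 simulated responses were read; 25 had an empty occupation cell and
were dropped. Of the 675 remaining, 458 (68 %) matched a lookup title
perfectly after normalization and received the proxy (221 office workers,
223 non-office workers, 14 unverifiable); the 217 simulated typos landed in
`fx/unmatched.csv` with their nearest title and Jaro distance, ready for
manual review. The same steps run unchanged on real files — a
classification export, a code-to-collar key, and any response table with
`ID` and `Occupation_swe` columns (column names are configurable).

The library mirrors the CLI: `build_lookup`, `clean_responses`,
`match_responses`, `summarize`, and friends are importable from
`officeproxy`.

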