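"""Reproduce the published lookup's summary counts from downloaded inputs.

The real inputs are not redistributable here and must be downloaded first:

* the Swedish occupation classification SSYK 2012 (Statistics Sweden),
  exported as a semicolon CSV with occupation-title / code / reference
  columns (see --title-column etc.);
* the code-to-collar translation key (Statistics Sweden), as CSV with
  Code / Category columns;
* optionally the published lookup (SSYK12_modified) and example response
  file (Occupation_response) from the Zenodo record accompanying them.

Given those paths, this script rebuilds the lookup and prints the counts
that characterize it: input titles (expected 8946), placeholder-coded
titles (48), unique reduced titles (6601), armed-forces reduced titles
(36), titles without a specific code (5), and the proxy distribution
No / Unverified / Yes (2968 / 83 / 3550).  A mismatch in the reduced-title
counts most likely localizes to the title-reduction delimiter rule, which
can be varied with --delimiters.

Usage:
    python scripts/reproduce_published.py --classification ssyk2012.csv \
        --key translation_key.csv [--published-lookup SSYK12_modified.csv] \
        [--responses Occupation_response.csv]
"""

from __future__ import annotations

import argparse
from collections import Counter

from officeproxy import io_formats
from officeproxy.key_builder import (
    build_lookup,
    reduce_title,
    resolve_placeholder_codes,
)
from officeproxy.normalize import normalize_text
from officeproxy.records import PLACEHOLDER_CODE, UNKNOWN_CODE


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--classification", required=True)
    parser.add_argument("--key", required=True)
    parser.add_argument("--published-lookup", default=None)
    parser.add_argument("--responses", default=None)
    parser.add_argument("--title-column", default=io_formats.CLASSIFICATION_TITLE_COLUMN)
    parser.add_argument("--code-column", default=io_formats.CLASSIFICATION_CODE_COLUMN)
    parser.add_argument("--reference-column",
                        default=io_formats.CLASSIFICATION_REFERENCE_COLUMN)
    parser.add_argument("--delimiters", default=",")
    args = parser.parse_args()

    entries = io_formats.read_classification(
        args.classification,
        title_column=args.title_column,
        code_column=args.code_column,
        reference_column=args.reference_column,
    )
    key = io_formats.read_translation_key(args.key)
    lookup = build_lookup(entries, key, tuple(args.delimiters))

    n_placeholder = sum(1 for e in entries if e.code == PLACEHOLDER_CODE)

    # classify each reduced title by its resolved codes: all leading-0 ->
    # armed forces; all "10000" -> no specific code
    codes_by_title: dict[str, list[str]] = {}
    for e in resolve_placeholder_codes(entries):
        codes_by_title.setdefault(
            normalize_text(reduce_title(e.title, tuple(args.delimiters))), []
        ).append(e.code)
    n_armed = sum(
        1 for codes in codes_by_title.values() if all(c.startswith("0") for c in codes)
    )
    n_no_code = sum(
        1 for codes in codes_by_title.values() if all(c == UNKNOWN_CODE for c in codes)
    )
    proxies = Counter(e.office_worker.value for e in lookup)

    print(f"input classification titles: {len(entries)}   (published: 8946)")
    print(f"placeholder-coded titles:    {n_placeholder}   (published: 48)")
    print(f"unique reduced titles:       {len(lookup)}   (published: 6601)")
    print(f"armed-forces reduced titles: {n_armed}   (published: 36)")
    print(f"titles without specific code: {n_no_code}   (published: 5)")
    print(f"proxy No:                    {proxies.get('No', 0)}   (published: 2968)")
    print(f"proxy Unverified:            {proxies.get('Unverified', 0)}   (published: 83)")
    print(f"proxy Yes:                   {proxies.get('Yes', 0)}   (published: 3550)")

    if args.published_lookup:
        published = io_formats.read_lookup(args.published_lookup)
        print(f"published lookup records:    {len(published)}   (published: 6864)")
    if args.responses:
        records = io_formats.read_responses(args.responses)
        print(f"response records:            {len(records)}   (published: 700)")


if __name__ == "__main__":
    main()
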