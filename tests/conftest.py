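from __future__ import annotations

import pytest

from officeproxy.records import (
    Category,
    ClassificationEntry,
    Collar,
    LookupEntry,
    OfficeWorker,
    TranslationKey,
)


@pytest.fixture
def toy_key() -> TranslationKey:
    """Prefix key: 1 manager, 2-4 white-collar, 5-9 blue-collar, 0 white
    (so the armed-forces override is what turns it unknown)."""
    entries = {"0": Collar.WHITE, "1": Collar.MANAGER}
    entries.update({d: Collar.WHITE for d in "234"})
    entries.update({d: Collar.BLUE for d in "56789"})
    return TranslationKey(entries)


@pytest.fixture
def toy_classification() -> list[ClassificationEntry]:
    """Five rows reducing to three distinct titles (two multi-code)."""
    return [
        ClassificationEntry("Civilingenjör, gruvteknik och metallurgi", "2146"),
        ClassificationEntry("Civilingenjör, elkraft", "2151"),
        ClassificationEntry("Snickare, inom byggverksamhet", "7115"),
        ClassificationEntry("Snickare, möbel", "7522"),
        ClassificationEntry("Lärare", "2341"),
    ]


def make_lookup_entry(
    title: str,
    office_worker: OfficeWorker = OfficeWorker.YES,
    *,
    from_standard: bool = True,
    n_codes: int = 1,
    proportion_white: float | None = None,
) -> LookupEntry:
    from officeproxy.normalize import normalize_text
    from officeproxy.records import PROXY_TO_CATEGORY

    if proportion_white is None and from_standard:
        proportion_white = 1.0 if office_worker is OfficeWorker.YES else 0.0
    return LookupEntry(
        title=title,
        normalized_title=normalize_text(title),
        from_standard=from_standard,
        n_codes=n_codes if from_standard else 0,
        proportion_white=proportion_white,
        category=PROXY_TO_CATEGORY[office_worker],
        office_worker=office_worker,
    )


@pytest.fixture
def toy_lookup() -> list[LookupEntry]:
    return [
        make_lookup_entry("Sjuksköterska", OfficeWorker.YES),
        make_lookup_entry("Snickare", OfficeWorker.NO),
        make_lookup_entry("Officer", OfficeWorker.UNVERIFIED, proportion_white=0.0),
    ]
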