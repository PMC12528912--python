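"""Lookup construction: placeholder resolution, categorization, majority vote."""

import itertools
import random

import pytest

from officeproxy.key_builder import (
    assign_proxy,
    build_lookup,
    categorize_code,
    collapse,
    majority_category,
    merge_supplemental,
    proportion_white,
    reduce_title,
    resolve_placeholder_codes,
)
from officeproxy.records import (
    Category,
    ClassificationEntry,
    CodeCounts,
    Collar,
    MajorityOutcome,
    OfficeWorker,
)

# ------------------------------------------------------ placeholder codes

def _ph(title, ref=None):
    return ClassificationEntry(title, "xxxx", reference_title=ref)


class TestResolvePlaceholders:
    def test_single_reference_takes_referred_code(self):
        entries = [ClassificationEntry("Gruvingenjör", "2146"), _ph("Bergsman", "Gruvingenjör")]
        out = resolve_placeholder_codes(entries)
        assert out[1].code == "2146"

    def test_common_prefix_zero_filled(self):
        entries = [
            ClassificationEntry("Tekniker", "3151"),
            ClassificationEntry("Tekniker", "3155"),
            _ph("Maskinist", "Tekniker"),
        ]
        assert resolve_placeholder_codes(entries)[2].code == "3150"

    def test_differing_first_digit_uses_majority(self):
        entries = [
            ClassificationEntry("Ingenjör", "2146"),
            ClassificationEntry("Ingenjör", "3112"),
            ClassificationEntry("Ingenjör", "2144"),
            _ph("Konstruktör", "Ingenjör"),
        ]
        assert resolve_placeholder_codes(entries)[3].code == "2000"

    def test_no_reference_gets_sentinel(self):
        out = resolve_placeholder_codes([_ph("Diversearbetare")])
        assert out[0].code == "10000"

    def test_dangling_reference_falls_back_to_sentinel(self, caplog):
        with caplog.at_level("WARNING"):
            out = resolve_placeholder_codes([_ph("Okänd", "Finns ej")])
        assert out[0].code == "10000"
        assert any("Finns ej" in r.message for r in caplog.records)

    def test_non_placeholders_pass_through_in_order(self):
        entries = [ClassificationEntry("A", "1111"), ClassificationEntry("B", "2222")]
        assert resolve_placeholder_codes(entries) == entries


# ----------------------------------------------------------- categorization

class TestCategorizeCode:
    def test_armed_forces_override(self, toy_key):
        # the key files leading-0 codes as white-collar; override wins
        assert toy_key.lookup("0110") is Collar.WHITE
        assert categorize_code("0110", toy_key) is Collar.UNKNOWN

    def test_sentinel_is_unknown(self, toy_key):
        assert categorize_code("10000", toy_key) is Collar.UNKNOWN

    def test_manager_folds_into_white(self, toy_key):
        assert categorize_code("1342", toy_key) is Collar.WHITE

    def test_plain_white_and_blue(self, toy_key):
        assert categorize_code("2146", toy_key) is Collar.WHITE
        assert categorize_code("7115", toy_key) is Collar.BLUE

    def test_code_absent_from_key_warns_unknown(self, caplog):
        from officeproxy.records import TranslationKey

        key = TranslationKey({"2": Collar.WHITE})
        with caplog.at_level("WARNING"):
            assert categorize_code("7115", key) is Collar.UNKNOWN
        assert any("7115" in r.message for r in caplog.records)


# ---------------------------------------------------------------- reduction

@pytest.mark.parametrize(
    ("title", "expected"),
    [
        ("Civilingenjör, gruvteknik och metallurgi", "Civilingenjör"),
        ("Snickare", "Snickare"),
        ("Lärare, grundskola, åk 1-3", "Lärare"),
        ("  Ekonom  ", "Ekonom"),
    ],
)
def test_reduce_title(title, expected):
    assert reduce_title(title) == expected


def test_reduce_title_empty_head_keeps_whole_title(caplog):
    with caplog.at_level("WARNING"):
        assert reduce_title(", ogiltig") == ", ogiltig"
    assert caplog.records


def test_reduce_title_custom_delimiters():
    assert reduce_title("Lärare/förskola", delimiters=(",", "/")) == "Lärare"


# ------------------------------------------------------------ majority vote

def majority_oracle(w: int, b: int, u: int) -> MajorityOutcome:
    """Argmax with the tie rules, written as explicit winner-set cases."""
    top = max(w, b, u)
    winners = {
        name for name, n in (("white", w), ("blue", b), ("unknown", u)) if n == top
    }
    if "white" in winners and "blue" in winners:
        return MajorityOutcome.TIED
    if "white" in winners:
        return MajorityOutcome.WHITE
    if "blue" in winners:
        return MajorityOutcome.BLUE
    return MajorityOutcome.UNKNOWN


@pytest.mark.parametrize(
    ("w", "b", "u", "expected"),
    [
        (3, 1, 0, MajorityOutcome.WHITE),
        (2, 2, 0, MajorityOutcome.TIED),
        (1, 0, 1, MajorityOutcome.WHITE),
        (0, 1, 1, MajorityOutcome.BLUE),
        (1, 1, 1, MajorityOutcome.TIED),
        (0, 0, 2, MajorityOutcome.UNKNOWN),
    ],
)
def test_majority_examples(w, b, u, expected):
    assert majority_category(CodeCounts(n_white=w, n_blue=b, n_unknown=u)) is expected


def test_majority_matches_oracle_exhaustively():
    for w, b, u in itertools.product(range(7), repeat=3):
        if not 1 <= w + b + u <= 6:
            continue
        counts = CodeCounts(n_white=w, n_blue=b, n_unknown=u)
        assert majority_category(counts) is majority_oracle(w, b, u), (w, b, u)


def test_majority_empty_counts_is_error():
    with pytest.raises(ValueError):
        majority_category(CodeCounts())


# ------------------------------------------------------- proportion & proxy

@pytest.mark.parametrize(
    ("counts", "expected"),
    [
        (CodeCounts(n_white=2, n_blue=1, n_unknown=1), 0.5),
        (CodeCounts(n_blue=3), 0.0),
        (CodeCounts(n_white=4), 1.0),
    ],
)
def test_proportion_white(counts, expected):
    assert proportion_white(counts) == expected


def test_proportion_white_empty_is_error():
    with pytest.raises(ValueError):
        proportion_white(CodeCounts())


@pytest.mark.parametrize(
    ("outcome", "expected"),
    [
        (MajorityOutcome.WHITE, OfficeWorker.YES),
        (MajorityOutcome.BLUE, OfficeWorker.NO),
        (MajorityOutcome.UNKNOWN, OfficeWorker.UNVERIFIED),
        (MajorityOutcome.TIED, OfficeWorker.UNVERIFIED),
    ],
)
def test_assign_proxy(outcome, expected):
    assert assign_proxy(outcome) is expected


def test_strict_white_majority_forces_yes_exhaustively():
    """proportion_white > 0.5 implies proxy Yes, for all tallies up to 8."""
    for w, b, u in itertools.product(range(9), repeat=3):
        if not 1 <= w + b + u <= 8:
            continue
        counts = CodeCounts(n_white=w, n_blue=b, n_unknown=u)
        if proportion_white(counts) > 0.5:
            assert assign_proxy(majority_category(counts)) is OfficeWorker.YES
        if proportion_white(counts) == 0.0 and u == 0:
            assert assign_proxy(majority_category(counts)) is OfficeWorker.NO


# ------------------------------------------------------------------ collapse

class TestCollapse:
    def test_groups_on_reduced_title(self, toy_classification, toy_key):
        lookup = collapse(toy_classification, toy_key)
        assert [e.title for e in lookup] == ["Civilingenjör", "Lärare", "Snickare"]
        by_title = {e.title: e for e in lookup}
        civ = by_title["Civilingenjör"]
        assert civ.n_codes == 2 and civ.counts.n_white == 2
        assert civ.office_worker is OfficeWorker.YES
        assert by_title["Snickare"].office_worker is OfficeWorker.NO

    def test_conservation_of_codes(self, toy_classification, toy_key):
        lookup = collapse(toy_classification, toy_key)
        assert sum(e.n_codes for e in lookup) == len(toy_classification)
        for e in lookup:
            c = e.counts
            assert c.n_white + c.n_blue + c.n_unknown == e.n_codes

    def test_armed_forces_contributes_unknown(self, toy_key):
        lookup = collapse([ClassificationEntry("Officer", "0110")], toy_key)
        assert lookup[0].counts.n_unknown == 1
        assert lookup[0].office_worker is OfficeWorker.UNVERIFIED

    def test_case_variants_merge_first_spelling_wins(self, toy_key):
        entries = [
            ClassificationEntry("Lärare, åk 1", "2341"),
            ClassificationEntry("LÄRARE, åk 2", "2342"),
        ]
        lookup = collapse(entries, toy_key)
        assert len(lookup) == 1
        assert lookup[0].title == "Lärare" and lookup[0].n_codes == 2

    def test_order_independence(self, toy_classification, toy_key):
        rng = random.Random(7)
        shuffled = list(toy_classification)
        rng.shuffle(shuffled)
        assert collapse(shuffled, toy_key) == collapse(toy_classification, toy_key)

    def test_unresolved_placeholder_rejected(self, toy_key):
        with pytest.raises(ValueError, match="placeholder"):
            collapse([ClassificationEntry("X", "xxxx")], toy_key)

    def test_build_lookup_resolves_then_collapses(self, toy_key):
        entries = [
            ClassificationEntry("Gruvingenjör", "2146"),
            ClassificationEntry("Bergsman", "xxxx", reference_title="Gruvingenjör"),
        ]
        lookup = build_lookup(entries, toy_key)
        by_title = {e.title: e for e in lookup}
        assert by_title["Bergsman"].office_worker is OfficeWorker.YES


# ---------------------------------------------------------------- supplement

class TestMergeSupplemental:
    def test_appends_flagged_entries(self, toy_lookup):
        merged = merge_supplemental(
            toy_lookup, [("Egen företagare", OfficeWorker.UNVERIFIED),
                         ("Banktjänsteman", OfficeWorker.YES)]
        )
        assert len(merged) == 5
        extra = merged[3:]
        assert all(not e.from_standard for e in extra)
        assert all(e.n_codes == 0 and e.proportion_white is None for e in extra)
        assert extra[1].category is Category.WHITE

    def test_duplicate_normalized_title_rejected(self, toy_lookup):
        with pytest.raises(ValueError, match="SNICKARE"):
            merge_supplemental(toy_lookup, [("SNICKARE!", OfficeWorker.NO)])

    def test_empty_extra_is_identity(self, toy_lookup):
        assert merge_supplemental(toy_lookup, []) == toy_lookup
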