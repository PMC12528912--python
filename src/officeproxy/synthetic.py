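"""Synthetic classifications, translation keys, and response files.

Every stage of the pipeline is testable without downloading the real
occupation standard: this module generates a toy classification whose
collar composition is known by construction, a consistent translation key,
and a response file mixing exact titles, case/symbol variants, typos and
missing cells — each carrying its ground-truth label.

The generated world mimics the real inputs structurally: 4-digit codes
whose first digit determines the collar band (1 manager, 2-4 white-collar,
5-9 blue-collar, 0 armed forces), multi-code titles that collapse to one
reduced occupation, and placeholder rows exercising every resolution rule.
It makes no attempt to mimic the real title or code frequency distribution.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .normalize import normalize_text
from .records import (
    PLACEHOLDER_CODE,
    Category,
    ClassificationEntry,
    Collar,
    LookupEntry,
    OfficeWorker,
    ResponseRecord,
    TranslationKey,
)

#: Swedish-like occupation stems; includes å/ä/ö so fixtures exercise
#: non-ASCII case folding.
_STEMS = (
    "lärare", "snickare", "sjuksköterska", "ingenjör", "ekonom", "målare",
    "förskollärare", "elektriker", "frisör", "läkare", "jurist", "kock",
    "undersköterska", "chaufför", "städare", "säljare", "översättare",
    "bagare", "tandläkare", "officer", "bibliotekarie", "rörmokare",
    "psykolog", "murare", "växtodlare", "apotekare", "svetsare", "barnmorska",
)
_PREFIXES = (
    "", "special", "över", "förste ", "biträdande ", "industri", "vård",
    "system", "drift", "miljö", "bygg", "data", "järnvägs", "sjö", "skogs",
)
#: Specializations appended after a comma on multi-code titles; the
#: reduction step cuts them away again.
_SPECIALIZATIONS = (
    "inom vård och omsorg", "inom byggverksamhet", "inom industri",
    "inom utbildning", "inom transport", "inom ekonomi och förvaltning",
    "inom handel", "övrig inriktning",
)

#: First digit of a generated code per collar band.
_FIRST_DIGITS = {
    Collar.MANAGER: "1",
    Collar.WHITE: "234",
    Collar.BLUE: "56789",
    Collar.UNKNOWN: "0",  # armed forces
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic world.

    ``collar_mix`` gives the probabilities that a generated occupation
    concept is (manager, white-collar, blue-collar, armed-forces,
    placeholder); ``p_exact``/``p_variant``/``p_typo``/``p_missing`` give
    the response mix.  Both must sum to 1.  Defaults approximate the
    published inputs: ~700 responses, a white/blue collar balance close to
    the real lookup's, and a response mix yielding roughly a 69 % match
    rate.
    """

    n_titles: int = 200
    codes_per_title: tuple[int, int] = (1, 3)
    collar_mix: tuple[float, float, float, float, float] = (
        0.08, 0.46, 0.43, 0.01, 0.02,
    )
    n_responses: int = 700
    p_exact: float = 0.45
    p_variant: float = 0.21
    p_typo: float = 0.30
    p_missing: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_titles < 1:
            raise ValueError("n_titles must be >= 1")
        if self.n_responses < 0:
            raise ValueError("n_responses must be >= 0")
        lo, hi = self.codes_per_title
        if not 1 <= lo <= hi:
            raise ValueError("codes_per_title must be a range with 1 <= lo <= hi")
        for name, probs in (
            ("collar_mix", self.collar_mix),
            ("response mix", (self.p_exact, self.p_variant, self.p_typo, self.p_missing)),
        ):
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")


@dataclass(frozen=True)
class TitleTruth:
    """Expected lookup-row fields for one reduced title, by construction."""

    title: str
    n_codes: int
    n_white: int
    n_blue: int
    n_unknown: int
    category: Category
    office_worker: OfficeWorker

    @property
    def proportion_white(self) -> float:
        return self.n_white / self.n_codes


@dataclass(frozen=True)
class ResponseTruth:
    """Ground truth for one generated response."""

    kind: str  # "exact" | "variant" | "typo" | "missing"
    title: Optional[str] = None
    office_worker: Optional[OfficeWorker] = None

    @property
    def expect_dropped(self) -> bool:
        return self.kind == "missing"

    @property
    def expect_unmatched(self) -> bool:
        return self.kind == "typo"


def _title_pool() -> list[str]:
    titles = []
    for prefix, stem in itertools.product(_PREFIXES, _STEMS):
        title = (prefix + stem).strip()
        titles.append(title[0].upper() + title[1:])
    return titles


def _proxy_for(collar: Collar) -> tuple[Category, OfficeWorker]:
    if collar in (Collar.MANAGER, Collar.WHITE):
        return Category.WHITE, OfficeWorker.YES
    if collar is Collar.BLUE:
        return Category.BLUE, OfficeWorker.NO
    return Category.UNVERIFIED, OfficeWorker.UNVERIFIED


def default_translation_key() -> TranslationKey:
    """Prefix-granularity key matching the generated code bands.

    Armed-forces codes (leading 0) are filed as white-collar, as the real
    key does; the pipeline overrides them to unknown.
    """
    entries = {"0": Collar.WHITE, "1": Collar.MANAGER}
    for d in "234":
        entries[d] = Collar.WHITE
    for d in "56789":
        entries[d] = Collar.BLUE
    return TranslationKey(entries)


def generate_classification(
    spec: FixtureSpec,
) -> tuple[list[ClassificationEntry], TranslationKey, dict[str, TitleTruth]]:
    """Generate a toy classification with known per-title ground truth.

    Returns the classification rows (shuffled, so nothing downstream may
    rely on input order), the translation key, and a map from normalized
    reduced title to its expected lookup fields.  Deterministic given
    ``spec.seed``.  When the collar mix gives placeholders positive mass,
    the four placeholder-resolution rules are exercised in rotation:
    single-reference, common-prefix codes, differing first digits, and no
    reference at all.
    """
    rng = random.Random(spec.seed)
    key = default_translation_key()
    pool = _title_pool()
    rng.shuffle(pool)
    # placeholders consume two titles each; letter suffixes (digits would be
    # stripped by normalization) keep extended titles distinct
    base, suffix_ord = list(pool), 0
    while len(pool) < 2 * spec.n_titles + 8:
        suffix = " " + chr(ord("b") + suffix_ord) * 2
        pool.extend(t + suffix for t in base)
        suffix_ord += 1

    entries: list[ClassificationEntry] = []
    truth: dict[str, TitleTruth] = {}
    collars = (Collar.MANAGER, Collar.WHITE, Collar.BLUE, Collar.UNKNOWN, "placeholder")
    placeholder_rule = 0
    pool_iter = iter(pool)

    def next_title() -> str:
        return next(pool_iter)

    def make_code(collar: Collar) -> str:
        return rng.choice(_FIRST_DIGITS[collar]) + f"{rng.randrange(1000):03d}"

    def emit_concept(collar: Collar, codes: Sequence[str], title: str) -> None:
        """Emit rows for one reduced-title concept of a single collar."""
        if len(codes) == 1:
            entries.append(ClassificationEntry(title=title, code=codes[0]))
        else:
            specs = rng.sample(_SPECIALIZATIONS, len(codes))
            for code, spc in zip(codes, specs):
                entries.append(
                    ClassificationEntry(title=f"{title}, {spc}", code=code)
                )
        cat, proxy = _proxy_for(collar)
        is_white = collar in (Collar.MANAGER, Collar.WHITE)
        truth[normalize_text(title)] = TitleTruth(
            title=title,
            n_codes=len(codes),
            n_white=len(codes) if is_white else 0,
            n_blue=len(codes) if collar is Collar.BLUE else 0,
            n_unknown=len(codes) if collar is Collar.UNKNOWN else 0,
            category=cat,
            office_worker=proxy,
        )

    def emit_placeholder(rule: int) -> None:
        """One placeholder row plus, for rules 0-2, its referenced concept."""
        ph_title = next_title()
        if rule == 0:
            ref_title = next_title()
            code = make_code(rng.choice((Collar.WHITE, Collar.BLUE)))
            entries.append(ClassificationEntry(title=ref_title, code=code))
            collar = Collar.WHITE if code[0] in "1234" else Collar.BLUE
            truth[normalize_text(ref_title)] = _single_truth(ref_title, collar)
            resolved, res_collar = code, collar
        elif rule == 1:
            # same referenced title twice, codes sharing leading digits
            ref_title = next_title()
            for code in ("3151", "3155"):
                entries.append(ClassificationEntry(title=ref_title, code=code))
            truth[normalize_text(ref_title)] = TitleTruth(
                title=ref_title, n_codes=2, n_white=2, n_blue=0, n_unknown=0,
                category=Category.WHITE, office_worker=OfficeWorker.YES,
            )
            resolved, res_collar = "3150", Collar.WHITE
        elif rule == 2:
            # differing first digits; majority first digit is 2
            ref_title = next_title()
            for code in ("2146", "3112", "2144"):
                entries.append(ClassificationEntry(title=ref_title, code=code))
            truth[normalize_text(ref_title)] = TitleTruth(
                title=ref_title, n_codes=3, n_white=3, n_blue=0, n_unknown=0,
                category=Category.WHITE, office_worker=OfficeWorker.YES,
            )
            resolved, res_collar = "2000", Collar.WHITE
        else:
            ref_title, resolved, res_collar = None, "10000", Collar.UNKNOWN
        entries.append(
            ClassificationEntry(
                title=ph_title, code=PLACEHOLDER_CODE, reference_title=ref_title
            )
        )
        truth[normalize_text(ph_title)] = _single_truth(ph_title, res_collar)

    def _single_truth(title: str, collar: Collar) -> TitleTruth:
        cat, proxy = _proxy_for(collar)
        is_white = collar in (Collar.MANAGER, Collar.WHITE)
        return TitleTruth(
            title=title, n_codes=1,
            n_white=1 if is_white else 0,
            n_blue=1 if collar is Collar.BLUE else 0,
            n_unknown=1 if not is_white and collar is not Collar.BLUE else 0,
            category=cat, office_worker=proxy,
        )

    for _ in range(spec.n_titles):
        choice = rng.choices(collars, weights=spec.collar_mix, k=1)[0]
        if choice == "placeholder":
            emit_placeholder(placeholder_rule % 4)
            placeholder_rule += 1
        else:
            k = rng.randint(*spec.codes_per_title)
            emit_concept(choice, [make_code(choice) for _ in range(k)], next_title())

    rng.shuffle(entries)
    return entries, key, truth


_VARIANT_SYMBOLS = (" - ", "/", "  ", "!", ".", " ")
_TYPO_ALPHABET = "abcdefghijklmnopqrstuvwxyzåäö"


def _make_variant(title: str, rng: random.Random) -> str:
    """Case/space/symbol perturbation that normalization undoes exactly."""
    text = rng.choice((title.upper(), title.lower(), title.capitalize(), title))
    if len(text) > 2 and rng.random() < 0.7:
        pos = rng.randrange(1, len(text) - 1)
        text = text[:pos] + rng.choice(_VARIANT_SYMBOLS) + text[pos:]
    if rng.random() < 0.5:
        text = " " + text + " "
    return text


def _make_typo(norm: str, forbidden: set[str], rng: random.Random) -> str:
    """Single-character edit of ``norm`` colliding with no lookup title."""
    for _ in range(100):
        ops = ["insert"]
        if len(norm) >= 2:
            ops += ["delete", "transpose"]
        op = rng.choice(ops)
        if op == "insert":
            pos = rng.randrange(len(norm) + 1)
            cand = norm[:pos] + rng.choice(_TYPO_ALPHABET) + norm[pos:]
        elif op == "delete":
            pos = rng.randrange(len(norm))
            cand = norm[:pos] + norm[pos + 1:]
        else:
            pos = rng.randrange(len(norm) - 1)
            if norm[pos] == norm[pos + 1]:
                continue  # no-op transposition
            cand = norm[:pos] + norm[pos + 1] + norm[pos] + norm[pos + 2:]
        if cand and cand not in forbidden:
            return cand
    # pathological vocabularies: extend until unique
    cand = norm + "q"
    while cand in forbidden:
        cand += "q"
    return cand


def generate_responses(
    spec: FixtureSpec,
    lookup: Sequence[LookupEntry],
) -> tuple[list[ResponseRecord], dict[str, ResponseTruth]]:
    """Generate responses against a lookup, with per-response ground truth.

    Each response is, with the spec's probabilities, an exact lookup title,
    a case/space/symbol variant of one (perfect match after normalization),
    a single-character typo of one (never matches any title), or a missing
    cell.  Ground truth is keyed by response id.  Deterministic given
    ``spec.seed``.
    """
    if not lookup:
        raise ValueError("lookup must be non-empty")
    rng = random.Random(spec.seed + 1)  # distinct stream from the classification
    normalized_titles = {e.normalized_title for e in lookup}
    kinds = ("exact", "variant", "typo", "missing")
    weights = (spec.p_exact, spec.p_variant, spec.p_typo, spec.p_missing)

    records: list[ResponseRecord] = []
    truth: dict[str, ResponseTruth] = {}
    for i in range(spec.n_responses):
        rid = str(i + 1)
        kind = rng.choices(kinds, weights=weights, k=1)[0]
        entry = rng.choice(lookup)
        if kind == "exact":
            text: Optional[str] = entry.title
            truth[rid] = ResponseTruth("exact", entry.title, entry.office_worker)
        elif kind == "variant":
            text = _make_variant(entry.title, rng)
            truth[rid] = ResponseTruth("variant", entry.title, entry.office_worker)
        elif kind == "typo":
            text = _make_typo(entry.normalized_title, normalized_titles, rng)
            truth[rid] = ResponseTruth("typo", entry.title)
        else:
            text = None if rng.random() < 0.5 else "  "
            truth[rid] = ResponseTruth("missing")
        records.append(ResponseRecord(id=rid, occupation_raw=text))
    return records, truth
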