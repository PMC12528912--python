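"""Readers and writers for the pipeline's four file roles.

All files are tables with a header row.  The canonical interchange format
is semicolon-separated CSV, UTF-8, with empty cells meaning missing values
and numbers written with a decimal point; ``.xlsx`` spreadsheets are
accepted read-only.  Column names are configurable everywhere, defaulting
to the published datasets' headers (``ID`` / ``Occupation_swe`` for
responses; ``Occupation title`` / ``From SSYK12`` / ``#SSYK12`` /
``Proportion white collar`` / ``Category`` / ``Office worker`` for the
lookup).
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .normalize import normalize_text
from .records import (
    PLACEHOLDER_CODE,
    PROXY_TO_CATEGORY,
    UNKNOWN_CODE,
    Category,
    ClassificationEntry,
    Collar,
    LookupEntry,
    MatchResult,
    OfficeWorker,
    ResponseRecord,
    TranslationKey,
)

PathLike = Union[str, Path]

SEPARATOR = ";"
ENCODING = "utf-8"

RESPONSE_ID_COLUMN = "ID"
RESPONSE_TEXT_COLUMN = "Occupation_swe"
RESPONSE_ENG_COLUMN = "Occupation_eng"

LOOKUP_COLUMNS = (
    "Occupation title",
    "From SSYK12",
    "#SSYK12",
    "Proportion white collar",
    "Category",
    "Office worker",
)

MATCH_COLUMNS = ("ID", "Occupation_swe", "Matched title", "Jaro distance", "Office worker")

CLASSIFICATION_TITLE_COLUMN = "Occupation title"
CLASSIFICATION_CODE_COLUMN = "Code"
CLASSIFICATION_REFERENCE_COLUMN = "Reference"

KEY_CODE_COLUMN = "Code"
KEY_CATEGORY_COLUMN = "Category"

_CODE_RE = re.compile(r"^(?:[0-9]{4}|xxxx|10000)$")

#: Accepted spellings of collar categories in translation-key files,
#: case-insensitive.  Swedish labels match the published key.
_COLLAR_LABELS = {
    "manager": Collar.MANAGER,
    "managers": Collar.MANAGER,
    "chef": Collar.MANAGER,
    "chefer": Collar.MANAGER,
    "white-collar": Collar.WHITE,
    "white collar": Collar.WHITE,
    "white": Collar.WHITE,
    "tjänsteman": Collar.WHITE,
    "tjänstemän": Collar.WHITE,
    "blue-collar": Collar.BLUE,
    "blue collar": Collar.BLUE,
    "blue": Collar.BLUE,
    "arbetare": Collar.BLUE,
}


def _is_spreadsheet(path: Path) -> bool:
    return path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}


def _read_table(
    path: PathLike,
    *,
    sheet: Union[int, str] = 0,
    header_row: int = 0,
) -> pd.DataFrame:
    """Read a CSV (semicolon dialect) or spreadsheet as all-string cells.

    Empty cells come back as empty strings.  Duplicate header names in a
    CSV are rejected (pandas would silently rename them).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if _is_spreadsheet(path):
        df = pd.read_excel(path, sheet_name=sheet, header=header_row, dtype=str)
        df = df.fillna("")
        # openpyxl surfaces integer cells as "2146.0"; undo that
        return df.map(
            lambda v: v[:-2]
            if isinstance(v, str) and v.endswith(".0") and v[:-2].isdigit()
            else v
        )
    else:
        with open(path, encoding=ENCODING, newline="") as fh:
            header = next(csv.reader(fh, delimiter=SEPARATOR), None)
        if header is not None:
            dupes = {c for c in header if header.count(c) > 1}
            if dupes:
                raise ValueError(
                    f"duplicate header names in {path}: {sorted(dupes)}"
                )
        df = pd.read_csv(
            path,
            sep=SEPARATOR,
            header=header_row,
            dtype=str,
            keep_default_na=False,
            encoding=ENCODING,
        )
    return df.fillna("")


def _require_columns(df: pd.DataFrame, names: Iterable[str], path: PathLike) -> None:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )


def _write_rows(path: PathLike, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding=ENCODING, newline="") as fh:
        writer = csv.writer(fh, delimiter=SEPARATOR, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


# ---------------------------------------------------------------- responses

def read_responses(
    path: PathLike,
    id_column: str = RESPONSE_ID_COLUMN,
    text_column: str = RESPONSE_TEXT_COLUMN,
    *,
    eng_column: str = RESPONSE_ENG_COLUMN,
    sheet: Union[int, str] = 0,
    header_row: int = 0,
) -> list[ResponseRecord]:
    """Read the questionnaire response file, one record per data row.

    Empty occupation cells yield a missing ``occupation_raw``; the optional
    English-translation column is carried along but never used.
    """
    df = _read_table(path, sheet=sheet, header_row=header_row)
    _require_columns(df, [id_column, text_column], path)
    has_eng = eng_column in df.columns
    records = []
    for i in range(len(df)):
        rid = str(df.iloc[i][id_column]).strip()
        text = str(df.iloc[i][text_column])
        if rid == "":
            raise ValueError(f"{path}: empty {id_column!r} in data row {i + 1}")
        eng = str(df.iloc[i][eng_column]) if has_eng else None
        records.append(
            ResponseRecord(
                id=rid,
                occupation_raw=text if text.strip() != "" else None,
                occupation_eng=eng if eng and eng.strip() != "" else None,
            )
        )
    return records


def write_responses(records: Sequence[ResponseRecord], path: PathLike) -> None:
    """Write responses in the semicolon dialect (fixture/export helper)."""
    _write_rows(
        path,
        (RESPONSE_ID_COLUMN, RESPONSE_TEXT_COLUMN, RESPONSE_ENG_COLUMN),
        (
            (r.id, r.occupation_raw or "", r.occupation_eng or "")
            for r in records
        ),
    )


# ----------------------------------------------------------- classification

def read_classification(
    path: PathLike,
    title_column: str = CLASSIFICATION_TITLE_COLUMN,
    code_column: str = CLASSIFICATION_CODE_COLUMN,
    reference_column: str = CLASSIFICATION_REFERENCE_COLUMN,
    *,
    sheet: Union[int, str] = 0,
    header_row: int = 0,
) -> list[ClassificationEntry]:
    """Read the raw occupation classification.

    Codes are preserved verbatim: 4-digit strings, the placeholder "xxxx",
    or the sentinel "10000"; anything else is an error.
    """
    df = _read_table(path, sheet=sheet, header_row=header_row)
    _require_columns(df, [title_column, code_column], path)
    has_ref = reference_column in df.columns
    entries = []
    for i in range(len(df)):
        title = str(df.iloc[i][title_column]).strip()
        code = str(df.iloc[i][code_column]).strip()
        if title == "":
            raise ValueError(f"{path}: empty title in data row {i + 1}")
        if not _CODE_RE.match(code):
            raise ValueError(
                f"{path}: unparseable code {code!r} in data row {i + 1} "
                f"(expected 4 digits, {PLACEHOLDER_CODE!r} or {UNKNOWN_CODE!r})"
            )
        ref = str(df.iloc[i][reference_column]).strip() if has_ref else ""
        entries.append(
            ClassificationEntry(
                title=title, code=code, reference_title=ref or None
            )
        )
    return entries


def write_classification(entries: Sequence[ClassificationEntry], path: PathLike) -> None:
    """Write a classification file (fixture/export helper)."""
    _write_rows(
        path,
        (
            CLASSIFICATION_TITLE_COLUMN,
            CLASSIFICATION_CODE_COLUMN,
            CLASSIFICATION_REFERENCE_COLUMN,
        ),
        ((e.title, e.code, e.reference_title or "") for e in entries),
    )


# ------------------------------------------------------------ translation key

def read_translation_key(
    path: PathLike,
    code_column: str = KEY_CODE_COLUMN,
    category_column: str = KEY_CATEGORY_COLUMN,
    *,
    sheet: Union[int, str] = 0,
    header_row: int = 0,
) -> TranslationKey:
    """Read the code -> collar translation key.

    Entries may be full 4-digit codes or shorter prefixes; lookup later
    uses the longest matching prefix.  Unknown category labels are errors.
    """
    df = _read_table(path, sheet=sheet, header_row=header_row)
    _require_columns(df, [code_column, category_column], path)
    entries: dict[str, Collar] = {}
    for i in range(len(df)):
        code = str(df.iloc[i][code_column]).strip()
        label = str(df.iloc[i][category_column]).strip()
        collar = _COLLAR_LABELS.get(label.casefold())
        if collar is None:
            raise ValueError(
                f"{path}: unknown category label {label!r} in data row {i + 1}"
            )
        entries[code] = collar
    return TranslationKey(entries)


def write_translation_key(key: TranslationKey, path: PathLike) -> None:
    """Write a translation key (fixture/export helper)."""
    _write_rows(
        path,
        (KEY_CODE_COLUMN, KEY_CATEGORY_COLUMN),
        sorted((prefix, collar.value) for prefix, collar in key.items()),
    )


# ------------------------------------------------------------------- lookup

def _format_float(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def _parse_float(cell: str, *, decimal_comma: bool = False) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    if decimal_comma:
        cell = cell.replace(",", ".")
    return float(cell)


def write_lookup(entries: Sequence[LookupEntry], path: PathLike) -> None:
    """Write the lookup table in its published six-column schema."""
    _write_rows(
        path,
        LOOKUP_COLUMNS,
        (
            (
                e.title,
                "Yes" if e.from_standard else "No",
                str(e.n_codes),
                _format_float(e.proportion_white),
                e.category.value,
                e.office_worker.value,
            )
            for e in entries
        ),
    )


def read_lookup(
    path: PathLike,
    *,
    sheet: Union[int, str] = 0,
    header_row: int = 0,
    decimal_comma: bool = False,
) -> list[LookupEntry]:
    """Read a lookup table; the normalized title is recomputed on the fly.

    ``decimal_comma=True`` accepts proportions written with a Swedish
    decimal comma.
    """
    df = _read_table(path, sheet=sheet, header_row=header_row)
    _require_columns(df, LOOKUP_COLUMNS, path)
    title_c, std_c, n_c, prop_c, cat_c, ow_c = LOOKUP_COLUMNS
    entries = []
    for i in range(len(df)):
        title = str(df.iloc[i][title_c]).strip()
        entries.append(
            LookupEntry(
                title=title,
                normalized_title=normalize_text(title),
                from_standard=str(df.iloc[i][std_c]).strip() == "Yes",
                n_codes=int(str(df.iloc[i][n_c]).strip() or 0),
                proportion_white=_parse_float(
                    str(df.iloc[i][prop_c]), decimal_comma=decimal_comma
                ),
                category=Category(str(df.iloc[i][cat_c]).strip()),
                office_worker=OfficeWorker(str(df.iloc[i][ow_c]).strip()),
            )
        )
    return entries


# ------------------------------------------------------------- match results

def write_matched(results: Sequence[MatchResult], path: PathLike) -> None:
    """Write match results; the proxy cell is empty for imperfect matches."""
    _write_rows(
        path,
        MATCH_COLUMNS,
        (
            (
                r.id,
                r.occupation_raw,
                r.best_title,
                _format_float(r.distance),
                r.office_worker.value if r.office_worker is not None else "",
            )
            for r in results
        ),
    )


def read_matched(
    path: PathLike,
    *,
    sheet: Union[int, str] = 0,
    header_row: int = 0,
) -> list[MatchResult]:
    """Read back a match-result file written by :func:`write_matched`."""
    df = _read_table(path, sheet=sheet, header_row=header_row)
    _require_columns(df, MATCH_COLUMNS, path)
    id_c, raw_c, title_c, dist_c, ow_c = MATCH_COLUMNS
    results = []
    for i in range(len(df)):
        raw = str(df.iloc[i][raw_c])
        ow = str(df.iloc[i][ow_c]).strip()
        results.append(
            MatchResult(
                id=str(df.iloc[i][id_c]).strip(),
                occupation_raw=raw,
                normalized=normalize_text(raw),
                best_title=str(df.iloc[i][title_c]),
                distance=_parse_float(str(df.iloc[i][dist_c])) or 0.0,
                office_worker=OfficeWorker(ow) if ow else None,
            )
        )
    return results


# ------------------------------------------------------------- supplemental

def read_supplemental(
    path: PathLike,
    title_column: str = "Occupation title",
    proxy_column: str = "Office worker",
    *,
    sheet: Union[int, str] = 0,
    header_row: int = 0,
) -> list[tuple[str, OfficeWorker]]:
    """Read a supplemental title list: title plus Yes/No/Unverified label."""
    df = _read_table(path, sheet=sheet, header_row=header_row)
    _require_columns(df, [title_column, proxy_column], path)
    out = []
    for i in range(len(df)):
        out.append(
            (
                str(df.iloc[i][title_column]).strip(),
                OfficeWorker(str(df.iloc[i][proxy_column]).strip()),
            )
        )
    return out
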