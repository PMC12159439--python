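"""ICD-10-style diagnosis code handling.

Codes are stored dot-less and uppercase: one letter followed by 2-4 digits
(3-5 characters). "Resolution" is the maximum code length considered, so a
native 3-character code such as ``K57`` is a valid member of a 4-character
code set. Chapter assignment follows the WHO ICD-10 chapter boundaries on
the 3-character prefix; prefixes that fall in a gap of the classification
(e.g. ``D49``) are rejected rather than silently mapped.

The burden metrics count, per participant, unique diagnosed conditions at
3- and 4-character resolution, both over all retained codes ("total") and
over a supplied set of disease-associated codes ("comorbid"), plus
chapter-wise and leave-one-chapter-out variants of the 3-character counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CODE_PATTERN",
    "CodeSet",
    "ExclusionRules",
    "BurdenProfile",
    "MalformedCodeError",
    "UnmappedCodeError",
    "normalize_code",
    "normalize_codes",
    "reduce_resolution",
    "chapter_of",
    "apply_exclusions",
    "count_burden",
    "burden_table",
    "endo_case_codes",
]

CODE_PATTERN = re.compile(r"^[A-Z][0-9]{2,4}$")

# WHO ICD-10 chapter boundaries as (first prefix, last prefix, chapter).
_CHAPTER_RANGES: list[tuple[str, str, int]] = [
    ("A00", "B99", 1),
    ("C00", "D48", 2),
    ("D50", "D89", 3),
    ("E00", "E90", 4),
    ("F00", "F99", 5),
    ("G00", "G99", 6),
    ("H00", "H59", 7),
    ("H60", "H95", 8),
    ("I00", "I99", 9),
    ("J00", "J99", 10),
    ("K00", "K93", 11),
    ("L00", "L99", 12),
    ("M00", "M99", 13),
    ("N00", "N99", 14),
    ("O00", "O99", 15),
    ("P00", "P96", 16),
    ("Q00", "Q99", 17),
    ("R00", "R99", 18),
    ("S00", "T98", 19),
    ("V01", "Y98", 20),
    ("Z00", "Z99", 21),
    ("U00", "U99", 22),
]


def _build_chapter_lookup() -> dict[str, int]:
    lookup: dict[str, int] = {}
    for lo, hi, chapter in _CHAPTER_RANGES:
        for letter_idx in range(ord(lo[0]), ord(hi[0]) + 1):
            letter = chr(letter_idx)
            start = int(lo[1:]) if letter == lo[0] else 0
            stop = int(hi[1:]) if letter == hi[0] else 99
            for num in range(start, stop + 1):
                lookup[f"{letter}{num:02d}"] = chapter
    return lookup


#: 3-character prefix -> chapter number (1..22); gaps absent.
CHAPTER_LOOKUP: dict[str, int] = _build_chapter_lookup()


class MalformedCodeError(ValueError):
    """Raised for inputs that cannot be normalized to a valid code."""

    def __init__(self, raw: str):
        self.raw = raw
        super().__init__(f"malformed diagnosis code: {raw!r}")


class UnmappedCodeError(ValueError):
    """Raised for syntactically valid prefixes lying in a classification gap."""

    def __init__(self, code: str):
        self.code = code
        super().__init__(f"code prefix not mapped to any chapter: {code!r}")


def normalize_code(raw: str) -> str:
    """Normalize a raw code: uppercase, strip one dot after position 3, validate.

    ``"N80.1"`` -> ``"N801"``; ``"k57"`` -> ``"K57"``. Raises
    :class:`MalformedCodeError` on anything that does not then match
    ``[A-Z][0-9]{2,4}``.
    """
    if not raw:
        raise MalformedCodeError(raw)
    code = raw.strip().upper()
    if len(code) > 3 and code[3] == ".":
        code = code[:3] + code[4:]
    if not CODE_PATTERN.match(code):
        raise MalformedCodeError(raw)
    return code


def normalize_codes(raw: Iterable[str]) -> list[str]:
    """Normalize a sequence of raw codes (vector convenience)."""
    return [normalize_code(r) for r in raw]


def reduce_resolution(code: str, level: int) -> str:
    """Truncate a code to at most ``level`` characters (3, 4 or 5).

    Codes already at or below ``level`` are returned unchanged.
    """
    if level not in (3, 4, 5):
        raise ValueError(f"resolution must be 3, 4 or 5, got {level}")
    return code[:level]


def chapter_of(code: str) -> int:
    """WHO ICD-10 chapter (1..22) of a normalized code's 3-character prefix."""
    try:
        return CHAPTER_LOOKUP[code[:3]]
    except KeyError:
        raise UnmappedCodeError(code) from None


@dataclass(frozen=True)
class CodeSet:
    """A set of codes at a declared maximum resolution.

    Membership respects truncation semantics: a code belongs to a
    4-character set iff its 4-character reduction is a member (so native
    3-character members match themselves).
    """

    codes: frozenset[str]
    resolution: int = 4
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "codes", frozenset(self.codes))
        for c in self.codes:
            if len(c) > self.resolution:
                raise ValueError(
                    f"code {c!r} exceeds declared resolution {self.resolution}"
                )

    def __contains__(self, code: str) -> bool:
        return reduce_resolution(code, self.resolution) in self.codes

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(sorted(self.codes))


#: Default explicit exclusions: the endometriosis codes N80.1-N80.9.
ENDOMETRIOSIS_SUBCODES = frozenset(f"N80{i}" for i in range(1, 10))


@dataclass(frozen=True)
class ExclusionRules:
    """Which codes are dropped before counting or set construction.

    Defaults drop the external-factor chapters 19 (injury/poisoning),
    20 (external causes) and 21 (health-status/contact factors), and the
    endometriosis diagnosis codes N80.1-N80.9 themselves. ``exclude_all_n80``
    additionally drops bare N80/N80.0 (off by default; the subcode range is
    the documented rule, see the methods note).
    """

    excluded_chapters: frozenset[int] = frozenset({19, 20, 21})
    excluded_codes: frozenset[str] = ENDOMETRIOSIS_SUBCODES
    exclude_all_n80: bool = False

    def __post_init__(self):
        object.__setattr__(self, "excluded_chapters", frozenset(self.excluded_chapters))
        object.__setattr__(self, "excluded_codes", frozenset(self.excluded_codes))
        bad = [c for c in self.excluded_chapters if not 1 <= c <= 22]
        if bad:
            raise ValueError(f"chapter numbers out of range 1..22: {bad}")

    def keeps(self, code: str) -> bool:
        if chapter_of(code) in self.excluded_chapters:
            return False
        if reduce_resolution(code, 4) in self.excluded_codes:
            return False
        if self.exclude_all_n80 and code[:3] == "N80":
            return False
        return True


def apply_exclusions(codes: Iterable[str], rules: ExclusionRules) -> list[str]:
    """Drop excluded codes, preserving order. Codes must be normalized."""
    return [c for c in codes if rules.keeps(c)]


@dataclass
class BurdenProfile:
    """Per-participant unique-diagnosis counts under every counting metric."""

    id: str
    total_3char: int = 0
    total_4char: int = 0
    comorbid_3char: int = 0
    comorbid_4char: int = 0
    per_chapter_total: dict[int, int] = field(default_factory=dict)
    per_chapter_comorbid: dict[int, int] = field(default_factory=dict)
    leave_one_out_total: dict[int, int] = field(default_factory=dict)
    leave_one_out_comorbid: dict[int, int] = field(default_factory=dict)


def count_burden(
    participant_id: str,
    raw_codes: Iterable[str],
    comorbid_set: CodeSet,
    rules: ExclusionRules | None = None,
) -> BurdenProfile:
    """Count one participant's diagnosis burden.

    Raw codes are normalized, filtered by ``rules``, then reduced;
    counts are of unique codes after reduction. A code contributes to the
    comorbid counts iff its 4-character reduction is a member of
    ``comorbid_set`` (the set is built at 4-character resolution by the
    association scan); the 3-character comorbid count is the number of
    unique 3-character stems among those codes. Chapter-wise and
    leave-one-chapter-out counts are derived from the 3-character sets.
    """
    if rules is None:
        rules = ExclusionRules()
    kept = apply_exclusions(normalize_codes(raw_codes), rules)

    four = {reduce_resolution(c, 4) for c in kept}
    three = {reduce_resolution(c, 3) for c in kept}
    com4 = {c for c in four if c in comorbid_set}
    com3 = {reduce_resolution(c, 3) for c in com4}

    profile = BurdenProfile(
        id=participant_id,
        total_3char=len(three),
        total_4char=len(four),
        comorbid_3char=len(com3),
        comorbid_4char=len(com4),
    )
    for stem in three:
        ch = chapter_of(stem)
        profile.per_chapter_total[ch] = profile.per_chapter_total.get(ch, 0) + 1
    for stem in com3:
        ch = chapter_of(stem)
        profile.per_chapter_comorbid[ch] = profile.per_chapter_comorbid.get(ch, 0) + 1
    for ch in range(1, 23):
        profile.leave_one_out_total[ch] = profile.total_3char - profile.per_chapter_total.get(ch, 0)
        profile.leave_one_out_comorbid[ch] = profile.comorbid_3char - profile.per_chapter_comorbid.get(ch, 0)
    return profile


def burden_table(
    diagnoses: pd.DataFrame,
    ids: Iterable[str],
    comorbid_set: CodeSet,
    rules: ExclusionRules | None = None,
) -> pd.DataFrame:
    """Vectorized burden counting for a whole cohort.

    Parameters
    ----------
    diagnoses
        Long-format table with columns ``id`` and ``code`` (normalized,
        dot-less codes).
    ids
        Every participant id the output must cover; participants with no
        retained codes get all-zero rows.
    comorbid_set
        4-character-resolution code set defining the comorbid metrics.
    rules
        Exclusion rules; defaults to :class:`ExclusionRules`.

    Returns
    -------
    DataFrame indexed by ``id`` with columns ``total_3char``, ``total_4char``,
    ``comorbid_3char``, ``comorbid_4char``, ``ch{1..22}_total`` and
    ``ch{1..22}_comorbid``. Leave-one-chapter-out counts are the 3-character
    totals minus the chapter column.
    """
    if rules is None:
        rules = ExclusionRules()
    ids = pd.Index(pd.unique(np.asarray(list(ids), dtype=object)), name="id")
    n_ids = len(ids)

    id_idx = ids.get_indexer(diagnoses["id"])
    if (id_idx < 0).any():
        bad = diagnoses.loc[id_idx < 0, "id"].iloc[0]
        raise ValueError(f"diagnosis id not in cohort: {bad!r}")

    # factorize codes once; all per-code work happens on the small unique array
    code_inv, codes_u = pd.factorize(diagnoses["code"].to_numpy(dtype=object))
    codes_u = np.asarray(codes_u, dtype=object)
    u4 = np.array([c[:4] for c in codes_u], dtype=object)
    u3 = np.array([c[:3] for c in codes_u], dtype=object)
    chap_u = np.array([CHAPTER_LOOKUP.get(p, -1) for p in u3], dtype=int)
    if (chap_u < 0).any():
        bad = sorted(codes_u[chap_u < 0][:10])
        raise UnmappedCodeError(", ".join(bad))
    keep_u = ~np.isin(chap_u, list(rules.excluded_chapters))
    keep_u &= np.array([c not in rules.excluded_codes for c in u4], dtype=bool)
    if rules.exclude_all_n80:
        keep_u &= u3 != "N80"

    cols = (
        ["total_3char", "total_4char", "comorbid_3char", "comorbid_4char"]
        + [f"ch{ch}_{kind}" for ch in range(1, 23) for kind in ("total", "comorbid")]
    )
    if len(codes_u) == 0 or not keep_u.any():
        return pd.DataFrame(0, index=ids, columns=cols)

    res = comorbid_set.resolution
    code4_u, c4_of = np.unique(u4, return_inverse=True)
    code3_u, c3_of = np.unique(u3, return_inverse=True)
    n4, n3 = len(code4_u), len(code3_u)
    comorbid4_u = np.array([c[:res] in comorbid_set.codes for c in code4_u], dtype=bool)
    chap3_u = np.array([CHAPTER_LOOKUP[p] for p in code3_u], dtype=int)

    keep = keep_u[code_inv]
    rid = id_idx[keep]
    r4 = c4_of[code_inv[keep]]
    r3 = c3_of[code_inv[keep]]
    rcom = comorbid4_u[r4]

    out = pd.DataFrame(index=ids)
    uk4 = np.unique(rid.astype(np.int64) * n4 + r4)
    uk3 = np.unique(rid.astype(np.int64) * n3 + r3)
    # comorbid 3-char stems: stems of codes whose 4-char form is in the set
    uk3c = np.unique(rid[rcom].astype(np.int64) * n3 + r3[rcom])
    out["total_3char"] = np.bincount(uk3 // n3, minlength=n_ids)
    out["total_4char"] = np.bincount(uk4 // n4, minlength=n_ids)
    out["comorbid_3char"] = np.bincount(uk3c // n3, minlength=n_ids)
    out["comorbid_4char"] = np.bincount(
        uk4[comorbid4_u[uk4 % n4]] // n4, minlength=n_ids
    )

    def _per_chapter(keys: np.ndarray) -> np.ndarray:
        ch = chap3_u[keys % n3]
        return np.bincount(
            (keys // n3) * 23 + ch, minlength=n_ids * 23
        ).reshape(n_ids, 23)

    cht = _per_chapter(uk3)
    chc = _per_chapter(uk3c)
    for ch in range(1, 23):
        out[f"ch{ch}_total"] = cht[:, ch]
        out[f"ch{ch}_comorbid"] = chc[:, ch]
    return out.astype(int)


def endo_case_codes(codes: Iterable[str]) -> bool:
    """True iff any code reduces to the 3-character endometriosis stem N80."""
    return any(reduce_resolution(normalize_code(c), 3) == "N80" for c in codes)
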