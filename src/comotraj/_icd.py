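"""ICD-10 vocabulary helpers: code range, chapters, age-group layers.

The analysis universe is three-character ICD-10 categories between A00 and
N99 (disease codes; encounter/injury chapters O–Z are excluded), plus one
sentinel code for hospitalized patients without any in-range diagnosis.
Codes are validated structurally (letter + two digits, string-ordered range
check); membership in the official WHO catalogue is deliberately not
checked.  The catalogue defines 1081 in-use categories in A00–N99; that
count is carried as a documented constant of the coding system.
"""

from __future__ import annotations

import re

#: regex every diagnosis code must match
CODE_PATTERN = re.compile(r"^[A-Z][0-9]{2}$")

#: default analysis range (inclusive; fixed-width strings order correctly)
CODE_RANGE = ("A00", "N99")

#: sentinel for hospitalized patients with no in-range diagnosis.  U codes
#: are reserved for special purposes in ICD-10, so U99 cannot collide with
#: a disease category.
SENTINEL = "U99"

#: number of in-use three-character ICD-10 categories in A00–N99
N_DISEASE_CATEGORIES = 1081

#: ten-year age-group layers: 1 -> 0–9y, ..., 8 -> 70–79y
AGE_GROUPS = tuple(range(1, 9))
AGE_GROUP_WIDTH = 10
MAX_AGE = 79  # ages 80+ fall outside the layer universe

# ICD-10 chapter blocks covering A00–N99 (chapter number, lo, hi).  Gap
# codes (e.g. D49) fall back to the block whose letter span contains them.
CHAPTERS = (
    ("I", "A00", "B99"),
    ("II", "C00", "D48"),
    ("III", "D50", "D89"),
    ("IV", "E00", "E90"),
    ("V", "F00", "F99"),
    ("VI", "G00", "G99"),
    ("VII", "H00", "H59"),
    ("VIII", "H60", "H95"),
    ("IX", "I00", "I99"),
    ("X", "J00", "J99"),
    ("XI", "K00", "K93"),
    ("XII", "L00", "L99"),
    ("XIII", "M00", "M99"),
    ("XIV", "N00", "N99"),
)


def is_valid_code(code: str) -> bool:
    """Structurally valid three-character code (letter + two digits)."""
    return bool(CODE_PATTERN.match(code))


def in_code_range(code: str, code_range: tuple[str, str] = CODE_RANGE) -> bool:
    """True if ``code`` lies inside the inclusive analysis range."""
    lo, hi = code_range
    return lo <= code <= hi


def chapter(code: str) -> str:
    """ICD-10 chapter numeral for a code in A00–N99 (or the sentinel).

    Codes falling in catalogue gaps are assigned to the nearest block with
    the same leading letter; the sentinel gets its own pseudo-chapter.
    """
    if code == SENTINEL:
        return "sentinel"
    for numeral, lo, hi in CHAPTERS:
        if lo <= code <= hi:
            return numeral
    for numeral, lo, hi in CHAPTERS:
        if lo[0] <= code[0] <= hi[0]:
            return numeral
    raise ValueError(f"code {code!r} outside A00-N99")


def age_band_to_group(age_band: int) -> int | None:
    """Map a 5-year band lower bound to a ten-year layer (1–8).

    Bands at or above 80 are outside the layer universe -> ``None``.
    """
    if age_band > MAX_AGE:
        return None
    return age_band // AGE_GROUP_WIDTH + 1


def node_label(code: str, age_group: int) -> str:
    """Render a (code, layer) node the way the network names them, e.g.
    ``E66-10-19`` for obesity in the second layer."""
    lo = (age_group - 1) * AGE_GROUP_WIDTH
    return f"{code}-{lo}-{lo + AGE_GROUP_WIDTH - 1}"


def parse_node_label(label: str) -> tuple[str, int]:
    code, lo, _hi = label.split("-")
    return code, int(lo) // AGE_GROUP_WIDTH + 1
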