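"""Reading, validating and serving note-onset annotations.

The unit of analysis throughout the package is the *individual
contribution*: one animal's part in a group song, represented by its
metadata (individual, sex, age) and the strictly increasing sequence of
note-onset times in seconds.  Annotations arrive either as Praat
TextGrid files (one interval tier of labelled notes) or as a flat onset
table (CSV, one row per note).

Age classes follow the three developmental stages used in studies of
indri song ontogeny: 0-2 years (up to 2.5), 3-4 years (2.6-4.5) and
adult (over 4.5).  The narrow gap the verbal definition leaves between
2.5 and 2.6 years is resolved by treating 2.5 as the exact boundary, so
the classes form a half-open partition of the age axis.
"""

from __future__ import annotations

import codecs
import csv
import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class AgeClass(enum.IntEnum):
    """Developmental stage; ordered YOUNG_0_2 < JUV_3_4 < ADULT."""

    YOUNG_0_2 = 0
    JUV_3_4 = 1
    ADULT = 2


def assign_age_class(age_years: float) -> AgeClass:
    """Map an age in years to its developmental stage.

    ``age_years <= 2.5`` is YOUNG_0_2, ``2.5 < age_years <= 4.5`` is
    JUV_3_4, anything above 4.5 is ADULT.  Monotone non-decreasing in
    ``age_years``.
    """
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        raise ValueError("age_years is missing; cannot assign an age class")
    if age_years < 0:
        raise ValueError(f"age_years must be nonnegative, got {age_years}")
    if age_years <= 2.5:
        return AgeClass.YOUNG_0_2
    if age_years <= 4.5:
        return AgeClass.JUV_3_4
    return AgeClass.ADULT


@dataclass(frozen=True)
class Contribution:
    """One individual's song contribution.

    ``onsets`` must be strictly increasing and nonnegative; ``offsets``,
    when present, pair with onsets and never precede them.
    """

    contribution_id: str
    individual_id: str
    sex: Sex
    age_years: float | None
    age_class: AgeClass
    song_id: str
    onsets: tuple[float, ...]
    offsets: tuple[float, ...] | None = None
    labels: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.onsets):
            raise ValueError(f"{self.contribution_id}: negative onset time")
        for a, b in zip(self.onsets, self.onsets[1:]):
            if b <= a:
                raise ValueError(
                    f"{self.contribution_id}: onsets not strictly increasing "
                    f"({a} followed by {b})"
                )
        if self.offsets is not None:
            if len(self.offsets) != len(self.onsets):
                raise ValueError(
                    f"{self.contribution_id}: {len(self.offsets)} offsets for "
                    f"{len(self.onsets)} onsets"
                )
            for on, off in zip(self.onsets, self.offsets):
                if off < on:
                    raise ValueError(
                        f"{self.contribution_id}: offset {off} precedes onset {on}"
                    )
        if self.age_years is not None and not math.isnan(self.age_years):
            expected = assign_age_class(self.age_years)
            if expected is not self.age_class:
                raise ValueError(
                    f"{self.contribution_id}: age_class {self.age_class.name} "
                    f"inconsistent with age_years {self.age_years} "
                    f"(expected {expected.name})"
                )

    @property
    def n_notes(self) -> int:
        return len(self.onsets)


class TextGridError(ValueError):
    """Raised for unreadable or malformed TextGrid files."""


_NUM_RE = re.compile(r"=\s*([-+0-9.eE]+)\s*$")
_STR_RE = re.compile(r'=\s*"(.*)"\s*$', re.DOTALL)


def _read_textgrid_text(path: Path) -> str:
    raw = path.read_bytes()
    # Praat writes long TextGrids either in UTF-8 or UTF-16 (with BOM).
    if raw.startswith(codecs.BOM_UTF16_LE) or raw.startswith(codecs.BOM_UTF16_BE):
        return raw.decode("utf-16")
    if raw.startswith(codecs.BOM_UTF8):
        return raw.decode("utf-8-sig")
    return raw.decode("utf-8")


def parse_textgrid(
    path: str | Path, tier_name: str
) -> list[tuple[float, float, str]]:
    """Extract labelled intervals from one tier of a long-format TextGrid.

    Returns ``(onset, offset, label)`` tuples for every interval of the
    named tier whose label is non-empty after stripping whitespace
    (empty labels are silences, not notes), ordered by onset.  Only the
    long text format is supported; the short format is rejected with an
    explicit message.

    Raises
    ------
    TextGridError
        If the file is missing, is not a long-format TextGrid, the tier
        does not exist or is not an interval tier, or a line cannot be
        parsed (the message names the line number).
    """
    path = Path(path)
    if not path.exists():
        raise TextGridError(f"TextGrid file not found: {path}")
    text = _read_textgrid_text(path)
    lines = text.splitlines()

    if not any("ooTextFile" in ln for ln in lines[:3]):
        raise TextGridError(f"{path}: not a Praat TextGrid (missing ooTextFile header)")
    # The short format carries bare values with no "name = value" lines.
    if not any("item" in ln and "[" in ln for ln in lines):
        raise TextGridError(
            f"{path}: looks like a short-format TextGrid; only the long text "
            "format is supported — re-save it from Praat as a full text file"
        )

    def num_at(i: int) -> float:
        m = _NUM_RE.search(lines[i])
        if not m:
            raise TextGridError(f"{path}:{i + 1}: expected a number, got {lines[i]!r}")
        return float(m.group(1))

    def str_at(i: int) -> str:
        m = _STR_RE.search(lines[i])
        if not m:
            raise TextGridError(f"{path}:{i + 1}: expected a string, got {lines[i]!r}")
        return m.group(1)

    intervals: list[tuple[float, float, str]] = []
    tier_found = False
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if "class" in line and "=" in line and "Object class" not in line:
            klass = str_at(i)
            # tier header: class, name, xmin, xmax, intervals/points: size
            j = i + 1
            while j < n and "name" not in lines[j]:
                j += 1
            if j >= n:
                break
            name = str_at(j)
            if name == tier_name:
                tier_found = True
                if klass != "IntervalTier":
                    raise TextGridError(
                        f"{path}: tier {tier_name!r} is a {klass}, not an IntervalTier"
                    )
                k = j + 1
                while k < n and "intervals: size" not in lines[k]:
                    k += 1
                if k >= n:
                    raise TextGridError(
                        f"{path}: tier {tier_name!r} has no 'intervals: size' line"
                    )
                size = int(num_at(k))
                k += 1
                for _ in range(size):
                    while k < n and "intervals [" not in lines[k]:
                        k += 1
                    if k + 3 >= n:
                        raise TextGridError(
                            f"{path}:{k + 1}: truncated interval block"
                        )
                    xmin = num_at(k + 1)
                    xmax = num_at(k + 2)
                    label = str_at(k + 3)
                    if label.strip():
                        intervals.append((xmin, xmax, label))
                    k += 4
                break
            i = j
        i += 1

    if not tier_found:
        raise TextGridError(f"{path}: tier {tier_name!r} not found")
    intervals.sort(key=lambda t: t[0])
    return intervals


ONSET_TABLE_COLUMNS = [
    "contribution_id",
    "individual_id",
    "sex",
    "age_years",
    "age_class",
    "song_id",
    "onset_s",
]


def read_onset_table(path: str | Path) -> list[Contribution]:
    """Read the canonical onset CSV into validated contributions.

    The table holds one row per note with columns ``contribution_id,
    individual_id, sex, age_years, age_class, song_id, onset_s`` and an
    optional ``offset_s``.  Rows are grouped by ``contribution_id``;
    onsets are sorted and must be free of duplicates within a
    contribution.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        missing = set(ONSET_TABLE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        has_offsets = "offset_s" in reader.fieldnames
        rows = list(reader)

    groups: dict[str, list[dict]] = {}
    for idx, row in enumerate(rows, start=2):  # header is line 1
        if row["sex"] not in {"F", "M"}:
            raise ValueError(
                f"{path}: line {idx}: unknown sex code {row['sex']!r} "
                "(expected F or M)"
            )
        groups.setdefault(row["contribution_id"], []).append({**row, "_line": idx})

    contributions: list[Contribution] = []
    for cid, grp in groups.items():
        grp.sort(key=lambda r: float(r["onset_s"]))
        onsets = tuple(float(r["onset_s"]) for r in grp)
        for a, b, r in zip(onsets, onsets[1:], grp[1:]):
            if b == a:
                raise ValueError(
                    f"{path}: line {r['_line']}: duplicate onset {b} in "
                    f"contribution {cid!r}"
                )
        first = grp[0]
        age_raw = first["age_years"].strip() if first["age_years"] else ""
        age_years = float(age_raw) if age_raw else None
        if first["age_class"]:
            age_class = AgeClass[first["age_class"]]
        elif age_years is not None:
            age_class = assign_age_class(age_years)
        else:
            raise ValueError(
                f"{path}: contribution {cid!r} has neither age_years nor age_class"
            )
        offsets = None
        if has_offsets and all(r.get("offset_s") for r in grp):
            offsets = tuple(float(r["offset_s"]) for r in grp)
        contributions.append(
            Contribution(
                contribution_id=cid,
                individual_id=first["individual_id"],
                sex=Sex(first["sex"]),
                age_years=age_years,
                age_class=age_class,
                song_id=first["song_id"],
                onsets=onsets,
                offsets=offsets,
            )
        )
    contributions.sort(key=lambda c: c.contribution_id)
    return contributions


def write_onset_table(contributions: Iterable[Contribution], path: str | Path) -> Path:
    """Write contributions to the canonical onset CSV (round-trip safe).

    Rows are sorted by contribution_id then onset; times are written
    with full float precision so ``read_onset_table`` recovers them
    exactly.
    """
    path = Path(path)
    contributions = sorted(contributions, key=lambda c: c.contribution_id)
    any_offsets = any(c.offsets is not None for c in contributions)
    cols = ONSET_TABLE_COLUMNS + (["offset_s"] if any_offsets else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for c in contributions:
            for i, onset in enumerate(c.onsets):
                row = [
                    c.contribution_id,
                    c.individual_id,
                    c.sex.value,
                    repr(c.age_years) if c.age_years is not None else "",
                    c.age_class.name,
                    c.song_id,
                    repr(onset),
                ]
                if any_offsets:
                    row.append(repr(c.offsets[i]) if c.offsets is not None else "")
                writer.writerow(row)
    return path


def contribution_from_intervals(
    intervals: Sequence[tuple[float, float, str]],
    *,
    contribution_id: str,
    individual_id: str,
    sex: Sex | str,
    age_years: float | None,
    song_id: str,
    age_class: AgeClass | None = None,
) -> Contribution:
    """Assemble a Contribution from ``parse_textgrid`` output plus metadata."""
    if age_class is None:
        if age_years is None:
            raise ValueError("either age_years or age_class is required")
        age_class = assign_age_class(age_years)
    return Contribution(
        contribution_id=contribution_id,
        individual_id=individual_id,
        sex=Sex(sex),
        age_years=age_years,
        age_class=age_class,
        song_id=song_id,
        onsets=tuple(t[0] for t in intervals),
        offsets=tuple(t[1] for t in intervals),
        labels=tuple(t[2] for t in intervals),
    )
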