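"""Inter-onset intervals, rhythmic ratios and small-integer-ratio bins.

For a sequence of note onsets the inter-onset interval (IOI) is
``t_k = onset[k+1] - onset[k]``.  The rhythmic ratio of two adjacent
IOIs is ``r_k = t_k / (t_k + t_{k+1})``, a dimensionless value in
(0, 1): isochrony (two equal intervals) gives 0.5, an interval followed
by one twice as long gives 1/3, the reverse gives 2/3.

Intervals longer than a cap (default 5 s) are treated as silences
between song parts rather than rhythmic intervals: they are discarded
and a *break* is recorded so that no ratio or interval triple ever
spans the gap.

The bin scheme places, around each small-integer ratio 1:2 (1/3),
1:1 (1/2) and 2:1 (2/3), an on-integer range flanked by two off-integer
ranges.  Boundaries are the exact fractions 1/3.5, 1/3.25, 1/2.75,
1/2.5, 1/2.25 and their complements, stored as :class:`~fractions.Fraction`
so the six ranges tile [1/3.5, 1 - 1/3.5] without gaps or overlaps.
Counting ratios per bin per contribution yields the response of the
peak-significance count model; the bin widths supply its offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .song_data import AgeClass, Contribution, Sex

DEFAULT_CAP_S = 5.0

CATEGORIES = ("R12", "R11", "R21")
#: reference points of the three rhythmic categories
CATEGORY_CENTRES = {
    "R12": Fraction(1, 3),
    "R11": Fraction(1, 2),
    "R21": Fraction(2, 3),
}
BIN_LABELS = ("on_R12", "off_R12", "on_R11", "off_R11", "on_R21", "off_R21")


@dataclass(frozen=True)
class IOISequence:
    """Capped inter-onset intervals with explicit sequence breaks.

    ``break_after`` holds the indices k such that the gap between
    ``values[k]`` and ``values[k+1]`` is not a real adjacency (an
    over-cap interval was discarded there); ratios and triples never
    bridge such an index.
    """

    values: tuple[float, ...]
    break_after: frozenset[int]
    cap: float = DEFAULT_CAP_S

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values):
            raise ValueError("IOI values must be positive")
        if any(v > self.cap for v in self.values):
            raise ValueError(f"IOI values must be <= cap ({self.cap} s)")
        if any(k < 0 or k >= len(self.values) for k in self.break_after):
            raise ValueError("break index out of range")

    def __len__(self) -> int:
        return len(self.values)

    def runs(self) -> list[tuple[float, ...]]:
        """Split values into maximal runs of truly adjacent intervals."""
        out: list[list[float]] = []
        current: list[float] = []
        for k, v in enumerate(self.values):
            current.append(v)
            if k in self.break_after:
                out.append(current)
                current = []
        if current:
            out.append(current)
        return [tuple(run) for run in out]


def compute_iois(
    contribution: Contribution | Sequence[float],
    cap: float = DEFAULT_CAP_S,
    *,
    bridge_gaps: bool = False,
) -> IOISequence:
    """Differences of successive onsets, capped at ``cap`` seconds.

    Intervals above the cap are discarded.  By default a break is
    recorded where an interval was dropped, so downstream ratios and
    triples never pair the intervals on either side of the gap; with
    ``bridge_gaps=True`` only the over-cap interval itself is removed
    and its neighbours are treated as adjacent.
    """
    onsets = (
        contribution.onsets
        if isinstance(contribution, Contribution)
        else tuple(contribution)
    )
    if len(onsets) == 0:
        raise ValueError("at least one onset is required")
    for a, b in zip(onsets, onsets[1:]):
        if b <= a:
            raise ValueError(f"onsets not strictly increasing: {a} then {b}")
    values: list[float] = []
    breaks: set[int] = set()
    for a, b in zip(onsets, onsets[1:]):
        t = b - a
        if t > cap:
            if values and not bridge_gaps:
                breaks.add(len(values) - 1)
        else:
            values.append(t)
    breaks.discard(len(values) - 1)  # trailing break is implied by the end
    return IOISequence(values=tuple(values), break_after=frozenset(breaks), cap=cap)


def compute_ratios(iois: IOISequence) -> list[float]:
    """Rhythmic ratios r_k = t_k / (t_k + t_{k+1}) for adjacent pairs.

    One ratio per pair of intervals not separated by a break; an empty
    or single-interval sequence yields an empty list.
    """
    out: list[float] = []
    for k in range(len(iois.values) - 1):
        if k in iois.break_after:
            continue
        a, b = iois.values[k], iois.values[k + 1]
        out.append(a / (a + b))
    return out


def compute_triples(iois: IOISequence) -> list[tuple[float, float, float]]:
    """Normalised triples of three consecutive intervals (ternary coordinates).

    Each window of three break-free consecutive intervals maps to
    ``(t_k, t_{k+1}, t_{k+2}) / sum``, a point on the 2-simplex;
    isochrony sits at the centre (1/3, 1/3, 1/3).
    """
    out: list[tuple[float, float, float]] = []
    for k in range(len(iois.values) - 2):
        if k in iois.break_after or (k + 1) in iois.break_after:
            continue
        a, b, c = iois.values[k], iois.values[k + 1], iois.values[k + 2]
        s = a + b + c
        out.append((a / s, b / s, c / s))
    return out


@dataclass(frozen=True)
class RatioBinScheme:
    """On/off-integer ranges around the small-integer ratios, as exact fractions.

    For each category the on-range ``[on_lo, on_hi)`` is flanked by
    ``[left_lo, on_lo)`` and ``[on_hi, right_hi)``.  Membership is
    half-open, except that the global maximum boundary is included in
    the last off-range so the scheme partitions its full span.
    """

    ranges: dict[str, tuple[Fraction, Fraction, Fraction, Fraction]]
    # per category: (left_off_lo, on_lo, on_hi, right_off_hi)

    @property
    def span(self) -> tuple[Fraction, Fraction]:
        los = [r[0] for r in self.ranges.values()]
        his = [r[3] for r in self.ranges.values()]
        return min(los), max(his)

    def on_range(self, category: str) -> tuple[Fraction, Fraction]:
        r = self.ranges[category]
        return r[1], r[2]

    def off_ranges(
        self, category: str
    ) -> tuple[tuple[Fraction, Fraction], tuple[Fraction, Fraction]]:
        r = self.ranges[category]
        return (r[0], r[1]), (r[2], r[3])

    def on_width(self, category: str) -> float:
        lo, hi = self.on_range(category)
        return float(hi - lo)

    def off_width(self, category: str) -> float:
        (a, b), (c, d) = self.off_ranges(category)
        return float((b - a) + (d - c))

    def width(self, bin_label: str) -> float:
        kind, cat = bin_label.split("_")
        return self.on_width(cat) if kind == "on" else self.off_width(cat)

    def all_boundaries(self) -> list[Fraction]:
        bs: set[Fraction] = set()
        for r in self.ranges.values():
            bs.update(r)
        return sorted(bs)


def default_bin_scheme() -> RatioBinScheme:
    """The three-category scheme with boundaries at 1/3.5 ... 1 - 1/3.5.

    Denominators 3.5, 3.25, 2.75, 2.5, 2.25 are stored as exact
    fractions (2/7, 4/13, 4/11, 2/5, 4/9) and their complements; the
    decimal forms usually quoted (0.286, 0.308, 0.364, 0.400, 0.444,
    0.556, 0.600, 0.636, 0.692, 0.714) are rounded displays only.
    """

    def inv(x: str) -> Fraction:
        return 1 / Fraction(x)

    b = {
        "3.5": inv("3.5"),
        "3.25": inv("3.25"),
        "2.75": inv("2.75"),
        "2.5": inv("2.5"),
        "2.25": inv("2.25"),
    }
    c = {k: 1 - v for k, v in b.items()}
    ranges = {
        "R12": (b["3.5"], b["3.25"], b["2.75"], b["2.5"]),
        "R11": (b["2.5"], b["2.25"], c["2.25"], c["2.5"]),
        "R21": (c["2.5"], c["2.75"], c["3.25"], c["3.5"]),
    }
    return RatioBinScheme(ranges=ranges)


def classify_ratio(r: float, scheme: RatioBinScheme | None = None) -> str | None:
    """Assign a ratio to its on/off bin, or None outside the covered span.

    Ranges are half-open [lo, hi); the global upper endpoint is included
    in the last off-range (off_R21 for the default scheme).
    """
    if not 0 < r < 1:
        raise ValueError(f"ratio must be strictly in (0, 1), got {r}")
    if scheme is None:
        scheme = default_bin_scheme()
    _, global_hi = scheme.span
    for cat, (left_lo, on_lo, on_hi, right_hi) in scheme.ranges.items():
        if on_lo <= r < on_hi:
            return f"on_{cat}"
        if left_lo <= r < on_lo:
            return f"off_{cat}"
        if on_hi <= r < right_hi:
            return f"off_{cat}"
        if right_hi == global_hi and r == float(global_hi):
            return f"off_{cat}"
    return None


@dataclass(frozen=True)
class BinCounts:
    """Per-contribution ratio counts per on/off bin, with bin widths."""

    contribution_id: str
    individual_id: str
    sex: Sex
    age_class: AgeClass
    counts: dict[str, int]
    widths: dict[str, float]
    n_ratios: int  # total ratios incl. those outside the covered span

    @property
    def n_unbinned(self) -> int:
        return self.n_ratios - sum(self.counts.values())


def count_bins(
    contribution: Contribution,
    scheme: RatioBinScheme | None = None,
    *,
    cap: float = DEFAULT_CAP_S,
    ratios: Sequence[float] | None = None,
) -> BinCounts:
    """Count a contribution's ratios in each on/off bin of the scheme.

    Ratios are computed from the contribution's onsets (capped IOIs,
    breaks respected) unless given explicitly.
    """
    if scheme is None:
        scheme = default_bin_scheme()
    if ratios is None:
        ratios = compute_ratios(compute_iois(contribution, cap=cap))
    counts = {label: 0 for label in BIN_LABELS}
    for r in ratios:
        label = classify_ratio(r, scheme)
        if label is not None:
            counts[label] += 1
    widths = {label: scheme.width(label) for label in BIN_LABELS}
    return BinCounts(
        contribution_id=contribution.contribution_id,
        individual_id=contribution.individual_id,
        sex=contribution.sex,
        age_class=contribution.age_class,
        counts=counts,
        widths=widths,
        n_ratios=len(ratios),
    )


# ---------------------------------------------------------------------------
# tabular views


def ratio_table(
    contributions: Iterable[Contribution],
    scheme: RatioBinScheme | None = None,
    cap: float = DEFAULT_CAP_S,
) -> pd.DataFrame:
    """Long table of every ratio with its bin label and metadata."""
    if scheme is None:
        scheme = default_bin_scheme()
    rows = []
    for c in contributions:
        ratios = compute_ratios(compute_iois(c, cap=cap))
        for k, r in enumerate(ratios):
            rows.append(
                {
                    "contribution_id": c.contribution_id,
                    "individual_id": c.individual_id,
                    "sex": c.sex.value,
                    "age_class": c.age_class.name,
                    "k": k,
                    "r_k": r,
                    "bin": classify_ratio(r, scheme) or "NONE",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contribution_id",
            "individual_id",
            "sex",
            "age_class",
            "k",
            "r_k",
            "bin",
        ],
    )


def ioi_table(
    contributions: Iterable[Contribution], cap: float = DEFAULT_CAP_S
) -> pd.DataFrame:
    """Long table of capped IOIs with metadata."""
    rows = []
    for c in contributions:
        iois = compute_iois(c, cap=cap)
        for k, t in enumerate(iois.values):
            rows.append(
                {
                    "contribution_id": c.contribution_id,
                    "individual_id": c.individual_id,
                    "sex": c.sex.value,
                    "age_class": c.age_class.name,
                    "k": k,
                    "t_k": t,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["contribution_id", "individual_id", "sex", "age_class", "k", "t_k"],
    )


def triples_table(
    contributions: Iterable[Contribution], cap: float = DEFAULT_CAP_S
) -> pd.DataFrame:
    """Long table of normalised interval triples (ternary coordinates)."""
    rows = []
    for c in contributions:
        for k, (a, b, d) in enumerate(compute_triples(compute_iois(c, cap=cap))):
            rows.append(
                {
                    "contribution_id": c.contribution_id,
                    "individual_id": c.individual_id,
                    "sex": c.sex.value,
                    "age_class": c.age_class.name,
                    "k": k,
                    "p1": a,
                    "p2": b,
                    "p3": d,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contribution_id",
            "individual_id",
            "sex",
            "age_class",
            "k",
            "p1",
            "p2",
            "p3",
        ],
    )


def bin_count_table(
    contributions: Iterable[Contribution],
    scheme: RatioBinScheme | None = None,
    cap: float = DEFAULT_CAP_S,
) -> pd.DataFrame:
    """Long (contribution x bin) table: the count model's input.

    Columns: contribution metadata, ``bin`` (on/off x category),
    ``count`` and ``width``; ``log(width)`` is the model offset.
    """
    if scheme is None:
        scheme = default_bin_scheme()
    rows = []
    for c in contributions:
        bc = count_bins(c, scheme, cap=cap)
        for label in BIN_LABELS:
            rows.append(
                {
                    "contribution_id": bc.contribution_id,
                    "individual_id": bc.individual_id,
                    "sex": bc.sex.value,
                    "age_class": bc.age_class.name,
                    "bin": label,
                    "count": bc.counts[label],
                    "width": bc.widths[label],
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "contribution_id",
            "individual_id",
            "sex",
            "age_class",
            "bin",
            "count",
            "width",
        ],
    )
    if len(df):
        df["log_width"] = np.log(df["width"])
    return df
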