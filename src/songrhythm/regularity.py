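"""Width-weighted rhythmic regularity around small-integer ratios.

Regularity quantifies how tightly the ratios near a rhythmic category
cluster in its on-integer range: each bin's count is weighted by its
width, and regularity is the weighted on-share

    regularity = (n_on * w_on) / (n_on * w_on + n_off * w_off)

so 1 means every near-category observation fell on-integer, 0 means
all fell off-integer, and the uneven widths of the on and off ranges do
not bias the proportion.  One record per contribution and category
feeds the beta mixed model of :mod:`songrhythm.glmm_stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .rhythm_core import BinCounts, RatioBinScheme, default_bin_scheme
from .song_data import AgeClass, Sex

#: categories modelled by default: those detected as significant in at
#: least two age classes of both sexes (isochrony and 1:2)
DEFAULT_CATEGORIES = ("R12", "R11")


def compute_regularity(
    n_on: int, n_off: int, w_on: float, w_off: float
) -> float:
    """Width-weighted on/(on+off) proportion; NaN when both counts are 0."""
    if n_on < 0 or n_off < 0:
        raise ValueError("counts must be nonnegative")
    if w_on <= 0 or w_off <= 0:
        raise ValueError("bin widths must be positive")
    if n_on + n_off == 0:
        return math.nan
    num = n_on * w_on
    return num / (num + n_off * w_off)


@dataclass(frozen=True)
class RegularityRecord:
    contribution_id: str
    individual_id: str
    sex: Sex
    age_class: AgeClass
    category: str
    n_on: int
    n_off: int
    regularity: float  # NaN when no near-category observations exist

    def __post_init__(self) -> None:
        if self.n_on + self.n_off == 0:
            if not math.isnan(self.regularity):
                raise ValueError("regularity must be missing when both counts are 0")
        elif not 0 <= self.regularity <= 1:
            raise ValueError("regularity must lie in [0, 1]")


def prepare_regularity_table(
    bin_counts: Iterable[BinCounts],
    scheme: RatioBinScheme | None = None,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    *,
    boundary_transform: bool = False,
) -> pd.DataFrame:
    """Per contribution x category regularity table for the beta model.

    Rows with no near-category observations carry NaN regularity and
    are excluded from modelling by the caller.  With
    ``boundary_transform=True`` the compression
    ``y' = (y (n - 1) + 0.5) / n`` (n = number of non-missing rows) maps
    the response into the open interval (0, 1) required by the beta
    likelihood.
    """
    if scheme is None:
        scheme = default_bin_scheme()
    records = []
    for bc in bin_counts:
        for cat in categories:
            if f"on_{cat}" not in bc.counts:
                raise KeyError(f"category {cat!r} not present in bin counts")
            n_on = bc.counts[f"on_{cat}"]
            n_off = bc.counts[f"off_{cat}"]
            records.append(
                RegularityRecord(
                    contribution_id=bc.contribution_id,
                    individual_id=bc.individual_id,
                    sex=bc.sex,
                    age_class=bc.age_class,
                    category=cat,
                    n_on=n_on,
                    n_off=n_off,
                    regularity=compute_regularity(
                        n_on, n_off, scheme.on_width(cat), scheme.off_width(cat)
                    ),
                )
            )
    df = pd.DataFrame(
        [
            {
                "contribution_id": r.contribution_id,
                "individual_id": r.individual_id,
                "sex": r.sex.value,
                "age_class": r.age_class.name,
                "category": r.category,
                "n_on": r.n_on,
                "n_off": r.n_off,
                "regularity": r.regularity,
            }
            for r in records
        ],
        columns=[
            "contribution_id",
            "individual_id",
            "sex",
            "age_class",
            "category",
            "n_on",
            "n_off",
            "regularity",
        ],
    )
    if boundary_transform and len(df):
        mask = df["regularity"].notna()
        n = int(mask.sum())
        if n > 0:
            y = df.loc[mask, "regularity"]
            df.loc[mask, "regularity"] = (y * (n - 1) + 0.5) / n
    return df
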