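"""Synthetic phrase-structured song contributions.

The generator emulates the statistical architecture the rhythm analysis
assumes in indri song, without touching audio: units are grouped into
phrases, so the inter-onset interval distribution is bimodal — short
within-phrase intervals with a mean near 2 s and long between-phrase
intervals near twice that — and the alternation of the two produces the
1:2 / 2:1 rhythmic ratio categories, while runs of equal within-phrase
intervals produce isochrony (1:1).

Age/sex presets capture the qualitative ontogenetic pattern: adult
song has tight interval dispersion and rapid phrase alternation (all
three categories emerge); young song has noisy, often over-cap
between-phrase gaps (so the 1:2/2:1 transitions are rare or smeared and
only isochrony survives), and young females additionally intersperse
single notes followed by long pauses.  Preset values are invented
calibration, not field estimates; they are chosen so the generated
cohorts reproduce the qualitative age/sex pattern, and they are the
study conditions for every downstream test.

Interval noise is gamma-distributed (positive support, parameterised by
mean and coefficient of variation); a per-individual lognormal tempo
multiplier induces the random-intercept grouping structure the mixed
models assume.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .song_data import AgeClass, Contribution, Sex

DEFAULT_CAP_S = 5.0


@dataclass(frozen=True)
class SyntheticClassParams:
    """Generative parameters for one age x sex class.

    ``between_multiplier`` scales the within-phrase mean IOI to give the
    between-phrase mean (2.0 yields the 1:2 / 2:1 categories exactly in
    the zero-noise limit).  ``p_long_pause`` is the probability that a
    between-phrase gap is an over-cap silence (> 5 s) rather than a
    rhythmic interval; ``p_single_note`` the probability that a phrase
    is a lone unit followed by a long pause.
    """

    mean_within_ioi: float  # seconds
    cv_within: float
    between_multiplier: float
    cv_between: float
    units_per_phrase_min: int
    units_per_phrase_mean: float
    n_phrases_mean: float
    p_single_note: float
    p_long_pause: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.mean_within_ioi <= 0 or self.between_multiplier <= 0:
            raise ValueError("interval means must be positive")
        if self.cv_within < 0 or self.cv_between < 0:
            raise ValueError("coefficients of variation must be nonnegative")
        if not (0 <= self.p_single_note <= 1 and 0 <= self.p_long_pause <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.units_per_phrase_min < 1:
            raise ValueError("units_per_phrase_min must be >= 1")
        if self.units_per_phrase_mean < self.units_per_phrase_min:
            raise ValueError("units_per_phrase_mean must be >= its minimum")


_PRESETS: dict[tuple[AgeClass, Sex], SyntheticClassParams] = {
    (AgeClass.ADULT, Sex.F): SyntheticClassParams(
        mean_within_ioi=2.0, cv_within=0.07, between_multiplier=2.0,
        cv_between=0.07, units_per_phrase_min=2, units_per_phrase_mean=4.0,
        n_phrases_mean=7.0, p_single_note=0.02, p_long_pause=0.05,
        label="adult female",
    ),
    (AgeClass.ADULT, Sex.M): SyntheticClassParams(
        mean_within_ioi=2.1, cv_within=0.07, between_multiplier=2.0,
        cv_between=0.07, units_per_phrase_min=2, units_per_phrase_mean=4.0,
        n_phrases_mean=7.0, p_single_note=0.02, p_long_pause=0.05,
        label="adult male",
    ),
    (AgeClass.JUV_3_4, Sex.F): SyntheticClassParams(
        mean_within_ioi=2.0, cv_within=0.10, between_multiplier=2.0,
        cv_between=0.15, units_per_phrase_min=2, units_per_phrase_mean=3.5,
        n_phrases_mean=6.0, p_single_note=0.15, p_long_pause=0.45,
        label="juvenile female",
    ),
    (AgeClass.JUV_3_4, Sex.M): SyntheticClassParams(
        mean_within_ioi=2.0, cv_within=0.12, between_multiplier=2.1,
        cv_between=0.35, units_per_phrase_min=2, units_per_phrase_mean=3.5,
        n_phrases_mean=6.0, p_single_note=0.05, p_long_pause=0.75,
        label="juvenile male",
    ),
    (AgeClass.YOUNG_0_2, Sex.F): SyntheticClassParams(
        mean_within_ioi=1.9, cv_within=0.14, between_multiplier=1.8,
        cv_between=0.40, units_per_phrase_min=1, units_per_phrase_mean=3.0,
        n_phrases_mean=6.0, p_single_note=0.50, p_long_pause=0.80,
        label="young female",
    ),
    (AgeClass.YOUNG_0_2, Sex.M): SyntheticClassParams(
        mean_within_ioi=2.0, cv_within=0.15, between_multiplier=2.0,
        cv_between=0.40, units_per_phrase_min=2, units_per_phrase_mean=3.0,
        n_phrases_mean=6.0, p_single_note=0.10, p_long_pause=0.85,
        label="young male",
    ),
}

#: representative ages (years) used to fill Contribution metadata
_CLASS_AGES = {AgeClass.YOUNG_0_2: 1.5, AgeClass.JUV_3_4: 3.5, AgeClass.ADULT: 8.0}


def default_class_params(age_class: AgeClass, sex: Sex) -> SyntheticClassParams:
    """The documented preset for one age x sex cell (see module docstring)."""
    return _PRESETS[(AgeClass(age_class), Sex(sex))]


def zero_noise_params(
    mean_within_ioi: float = 2.0,
    units_per_phrase_mean: float = 4.0,
    n_phrases_mean: float = 7.0,
) -> SyntheticClassParams:
    """Deterministic limit: no jitter, no long pauses, no single notes.

    Every generated ratio is exactly 1/3, 1/2 or 2/3, which pins the
    pipeline's classification and regularity stages.
    """
    return SyntheticClassParams(
        mean_within_ioi=mean_within_ioi, cv_within=0.0, between_multiplier=2.0,
        cv_between=0.0, units_per_phrase_min=2,
        units_per_phrase_mean=units_per_phrase_mean,
        n_phrases_mean=n_phrases_mean, p_single_note=0.0, p_long_pause=0.0,
        label="zero-noise",
    )


def _gamma(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0:
        return mean
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean / shape))


def _long_pause(rng: np.random.Generator, cap: float) -> float:
    # over-cap silence between song parts; magnitude is irrelevant
    # downstream (the interval is discarded), only the break matters
    return cap + 0.5 + float(rng.exponential(2.0))


def simulate_contribution(
    params: SyntheticClassParams,
    rng_seed: int | np.random.Generator,
    *,
    tempo: float = 1.0,
    cap: float = DEFAULT_CAP_S,
    contribution_id: str = "sim-0",
    individual_id: str = "ind-0",
    song_id: str = "song-0",
    sex: Sex = Sex.F,
    age_class: AgeClass = AgeClass.ADULT,
) -> Contribution:
    """Generate one phrase-structured contribution.

    Phrase count, units per phrase and interval durations are drawn
    from the preset's shifted-Poisson / gamma distributions; ``tempo``
    multiplies every interval mean (the individual random effect).
    Deterministic given the seed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n_phrases = 1 + int(rng.poisson(max(params.n_phrases_mean - 1, 0)))
    m_within = params.mean_within_ioi * tempo
    m_between = params.between_multiplier * m_within
    t = 0.0
    onsets = [t]
    for phrase in range(n_phrases):
        if rng.random() < params.p_single_note:
            units = 1
        else:
            units = params.units_per_phrase_min + int(
                rng.poisson(params.units_per_phrase_mean - params.units_per_phrase_min)
            )
        for _ in range(units - 1):
            t += _gamma(rng, m_within, params.cv_within)
            onsets.append(t)
        if phrase < n_phrases - 1:
            if units == 1 or rng.random() < params.p_long_pause:
                t += _long_pause(rng, cap)
            else:
                t += _gamma(rng, m_between, params.cv_between)
            onsets.append(t)
    # the last appended onset opens the next phrase; when the loop ends on
    # a between-gap the final onset is the first unit of the last phrase,
    # which is correct: every onset is a produced note
    age = _CLASS_AGES[age_class]
    return Contribution(
        contribution_id=contribution_id,
        individual_id=individual_id,
        sex=sex,
        age_years=age,
        age_class=age_class,
        song_id=song_id,
        onsets=tuple(onsets),
    )


def simulate_cohort(
    param_map: Mapping[tuple[AgeClass, Sex], SyntheticClassParams] | None = None,
    n_individuals: int = 20,
    contributions_each: int = 5,
    seed: int = 0,
    *,
    tempo_sd: float = 0.1,
    cap: float = DEFAULT_CAP_S,
) -> list[Contribution]:
    """Generate a cohort across age x sex cells with individual structure.

    Each individual carries a lognormal tempo multiplier
    (``exp(N(0, tempo_sd^2))``) shared by all its contributions — the
    random-intercept structure the mixed models assume.  With
    ``param_map=None`` all six default presets are used.
    """
    if param_map is None:
        param_map = dict(_PRESETS)
    if not param_map:
        raise ValueError("param_map must contain at least one (age_class, sex) cell")
    if n_individuals < 1 or contributions_each < 1:
        raise ValueError("need at least one individual and one contribution per cell")
    rng = np.random.default_rng(seed)
    out: list[Contribution] = []
    counter = itertools.count()
    for (age_class, sex), params in sorted(
        param_map.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        for i in range(n_individuals):
            ind_id = f"{age_class.name}_{sex.value}_ind{i:03d}"
            tempo = float(np.exp(rng.normal(0.0, tempo_sd))) if tempo_sd > 0 else 1.0
            for j in range(contributions_each):
                n = next(counter)
                out.append(
                    simulate_contribution(
                        params,
                        rng,
                        tempo=tempo,
                        cap=cap,
                        contribution_id=f"contrib{n:05d}",
                        individual_id=ind_id,
                        song_id=f"song{n:05d}",
                        sex=sex,
                        age_class=age_class,
                    )
                )
    return out
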