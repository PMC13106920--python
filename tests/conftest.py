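import textwrap
from pathlib import Path

import pytest

from songrhythm import AgeClass, Contribution, Sex


def make_contribution(onsets, cid="c1", ind="i1", sex=Sex.F, age=8.0, song="s1"):
    from songrhythm import assign_age_class

    return Contribution(
        contribution_id=cid,
        individual_id=ind,
        sex=sex,
        age_years=age,
        age_class=assign_age_class(age),
        song_id=song,
        onsets=tuple(onsets),
    )


TEXTGRID_LONG = textwrap.dedent('''\
    File type = "ooTextFile"
    Object class = "TextGrid"

    xmin = 0
    xmax = 6
    tiers? <exists>
    size = 1
    item []:
        item [1]:
            class = "IntervalTier"
            name = "notes"
            xmin = 0
            xmax = 6
            intervals: size = 6
            intervals [1]:
                xmin = 0.0
                xmax = 0.8
                text = "n1"
            intervals [2]:
                xmin = 0.8
                xmax = 2.0
                text = ""
            intervals [3]:
                xmin = 2.0
                xmax = 2.9
                text = "n2"
            intervals [4]:
                xmin = 2.9
                xmax = 4.1
                text = ""
            intervals [5]:
                xmin = 4.1
                xmax = 5.0
                text = "n3"
            intervals [6]:
                xmin = 5.0
                xmax = 6.0
                text = "   "
''')


@pytest.fixture
def textgrid_path(tmp_path: Path) -> Path:
    p = tmp_path / "song.TextGrid"
    p.write_text(TEXTGRID_LONG, encoding="utf-8")
    return p


@pytest.fixture
def textgrid_utf16_path(tmp_path: Path) -> Path:
    p = tmp_path / "song16.TextGrid"
    p.write_bytes(TEXTGRID_LONG.encode("utf-16"))  # with BOM, as Praat writes
    return p


@pytest.fixture
def two_contributions():
    c1 = make_contribution([0.0, 2.0, 4.0], cid="c1", ind="iA", sex=Sex.F, age=8.0)
    c2 = make_contribution([0.0, 1.5, 3.0, 4.5], cid="c2", ind="iA", sex=Sex.F, age=8.0)
    return [c1, c2]
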