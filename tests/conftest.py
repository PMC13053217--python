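import numpy as np
import pytest

from kelpshift.data_model import PairedQuadrat, QuadratSurvey


def make_survey(qid="Q0", year=1972, depth=1.0, cover=None, substrate=("bedrock",)):
    return QuadratSurvey(
        quadrat_id=qid,
        transect_id="T0",
        year=year,
        depth_m=depth,
        substrate=frozenset(substrate),
        cover=cover or {},
    )


def make_pair(qid="Q0", depth=1.0, hist_cover=None, mod_cover=None,
              hist_sub=("bedrock",), mod_sub=("bedrock",)):
    return PairedQuadrat(
        quadrat_id=qid,
        historical=make_survey(qid, 1972, depth, hist_cover, hist_sub),
        modern=make_survey(qid, 2023, depth, mod_cover, mod_sub),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
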