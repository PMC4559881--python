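import numpy as np
import pytest

from bacekit import ConcentrationTimeProfile, gen_section_image, quantify_section


def make_profile(times, conc, **kw):
    kw.setdefault("subject_id", "s1")
    kw.setdefault("matrix", "blood")
    return ConcentrationTimeProfile(
        times=np.asarray(times, float), concentrations=np.asarray(conc, float), **kw
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture(scope="session")
def standard_section():
    """The standard synthetic section fixture (seed 0) with its quantification."""
    section = gen_section_image(seed=0)
    quant = quantify_section(
        section.rgb, section.roi_mask, gfap=section.gfap, iba1=section.iba1
    )
    return section, quant
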