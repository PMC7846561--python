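import numpy as np
import pytest

from nanosyn.annotations_io import Dataset, ProfileAnnotation


def make_profile(
    synapse_id="syn1",
    section_index=0,
    thickness=40.0,
    condition="rest",
    label="AMPA",
    gold=(),
    pits=(),
    docked=(),
    half=100.0,
):
    return ProfileAnnotation(
        synapse_id=synapse_id,
        section_index=section_index,
        section_thickness_nm=thickness,
        condition=condition,
        label=label,
        az_trace=[[-half, 0.0], [half, 0.0]],
        psd_trace=[[-half, 0.0], [half, 0.0]],
        gold=[list(p) for p in gold],
        pits=[list(p) for p in pits],
        docked_vesicles=[list(p) for p in docked],
    )


@pytest.fixture
def small_dataset():
    """Two synapses, three profiles, with a few annotated points."""
    return Dataset(
        profiles=[
            make_profile("synA", 0, gold=[(0.0, 5.0), (40.0, -3.0)], pits=[(10.0, 0.0)]),
            make_profile("synA", 1, gold=[(-20.0, 2.0)], docked=[(0.0, 1.0)]),
            make_profile("synB", 0, gold=[(90.0, 0.0)]),
        ],
        provenance={"source": "fixture"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
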