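import numpy as np
import pytest

from qivivekit import params
from qivivekit.kinetics import EnzymeKinetics
from qivivekit.pbk import CompoundParams, SpeciesPhysiology, build_pbk


@pytest.fixture(scope="session")
def rat_model():
    return params.load_model("rat")


@pytest.fixture(scope="session")
def human_model():
    return params.load_model("human")


@pytest.fixture(scope="session")
def rpf_table():
    return params.load_rpf_table()


@pytest.fixture
def simple_physiology():
    """Small, valid physiology for constructed-model tests."""
    return SpeciesPhysiology(
        species="rat",
        body_weight=0.25,
        volume_fractions={
            "liver": 0.034,
            "kidney": 0.007,
            "fat": 0.07,
            "richly": 0.05,
            "slowly": 0.676,
            "blood": 0.074,
        },
        flow_fractions={
            "liver": 0.183,
            "kidney": 0.141,
            "fat": 0.07,
            "richly": 0.27,
            "slowly": 0.336,
        },
        cardiac_output=5.38,
        gfr=5.2,
    )


def make_compound(name="parent", **overrides):
    base = dict(
        name=name,
        molar_mass=270.24,
        partition={"liver": 1.0, "kidney": 1.0, "fat": 1.0, "richly": 1.0, "slowly": 1.0},
        bpr=1.0,
        fup=1.0,
        ka=0.5,
        fa=1.0,
        kb=0.0,
        pathways=[],
        clint=0.0,
    )
    base.update(overrides)
    return CompoundParams(**base)


def tiny_conversion(vmax=1e-30, km=1.0):
    """A negligible conversion pathway (models require exactly one)."""
    return EnzymeKinetics(
        vmax_unscaled=max(vmax, 1e-300), km=km, pathway="rhein_formation", vmax_scaled=vmax
    )


@pytest.fixture
def inert_model(simple_physiology):
    """All partitions 1, effectively no metabolism, no excretion."""
    parent = make_compound("parent", pathways=[tiny_conversion()])
    metabolite = make_compound("metabolite", ka=0.0, fa=0.0)
    physio = simple_physiology
    physio.gfr = 0.0
    return build_pbk(physio, parent, metabolite)
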