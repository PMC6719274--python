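import dataclasses

import numpy as np
import pytest

from infarctvol import (
    CTInfarctModel,
    IICParams,
    LesionSpec,
    PhantomSpec,
    correct_em_seg,
    correct_hist_sharpen,
    default_lesion_center,
    extract_brain,
    insert_lesion,
    make_head_phantom,
)

#: small, fast phantom for unit tests (brain ~520 cc)
SMALL = dict(
    grid=(48, 48, 16),
    spacing=(3.75, 3.75, 5.0),
    brain_semiaxes=(60.0, 70.0, 30.0),
)


def small_spec(**kw) -> PhantomSpec:
    merged = {**SMALL, "seed": 11, **kw}
    return PhantomSpec(**merged)


@pytest.fixture(scope="session")
def cupping_spec() -> PhantomSpec:
    """Default-geometry phantom spec: cupping 3 HU, noise 2 HU."""
    return PhantomSpec(seed=3)


@pytest.fixture(scope="session")
def cupping_phantom(cupping_spec):
    return make_head_phantom(cupping_spec)


@pytest.fixture(scope="session")
def brain_mask(cupping_phantom):
    return extract_brain(cupping_phantom.image)


@pytest.fixture(scope="session")
def em_result(cupping_phantom, brain_mask):
    return correct_em_seg(cupping_phantom.image, brain_mask, IICParams())


@pytest.fixture(scope="session")
def hist_result(cupping_phantom, brain_mask):
    return correct_hist_sharpen(
        cupping_phantom.image, brain_mask, IICParams(backend="hist_sharpen")
    )


@pytest.fixture(scope="session")
def iic_results(em_result, hist_result):
    return {"em_seg": em_result, "hist_sharpen": hist_result}


@pytest.fixture(scope="session")
def lesioned45(cupping_spec):
    """45 cc right-sided sphere at 20% density reduction, default phantom."""
    truth = make_head_phantom(cupping_spec)
    lesion = LesionSpec(
        shape="sphere",
        center=default_lesion_center(cupping_spec, "right"),
        target_volume_cc=45.0,
        density_reduction=0.20,
        side="right",
    )
    return insert_lesion(truth, lesion)


@pytest.fixture(scope="session")
def lesioned45_fit(lesioned45):
    return CTInfarctModel(lesioned45.image).fit(backend="em_seg", side="right")
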