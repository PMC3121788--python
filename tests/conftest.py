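import numpy as np
import pytest

from nmloops.types import (
    AccessibilityProfile,
    Loop,
    MatrixAttachmentRegion,
    NucleoidModel,
)


def bare_loop(length_bp: float, left_fp: float = 0.0, right_fp: float = 0.0,
              loop_id: str = "loop") -> Loop:
    return Loop(
        loop_id=loop_id,
        total_bp=float(length_bp),
        mars=(
            MatrixAttachmentRegion(loop_id, "left", float(left_fp)),
            MatrixAttachmentRegion(loop_id, "right", float(right_fp)),
        ),
    )


@pytest.fixture
def default_profile() -> AccessibilityProfile:
    return AccessibilityProfile(k0=2.0e-4, alpha=2.0)


@pytest.fixture
def single_loop_model(default_profile) -> NucleoidModel:
    loop = bare_loop(42_000.0, 420.0, 420.0)
    return NucleoidModel(loops=[loop], profile=default_profile, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
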