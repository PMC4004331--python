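"""Shared fixtures: synthetic communities reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from gutcrispr.simulate import (
    DetectorAgreement,
    SimulationConfig,
    emit_detector_predictions,
    generate_community,
)

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def noise_free_community():
    """Community with exact detector agreement and no decoys."""
    cfg = SimulationConfig(seed=11, n_decoys=0)
    contigs, cas, truth = generate_community(cfg)
    predictions = emit_detector_predictions(
        contigs, truth, DetectorAgreement(boundary_jitter=0), seed=12
    )
    return contigs, cas, truth, predictions


@pytest.fixture(scope="session")
def noisy_community():
    """Community with detector false negatives and planted decoys."""
    cfg = SimulationConfig(seed=21, n_decoys=8)
    contigs, cas, truth = generate_community(cfg)
    agreement = DetectorAgreement(
        fn_rate={"CRT": 0.3, "CFI": 0.3, "PIL": 0.3}, boundary_jitter=0
    )
    predictions = emit_detector_predictions(contigs, truth, agreement, seed=22)
    return contigs, cas, truth, predictions
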