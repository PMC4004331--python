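"""Statistical calibration studies for the spacer-position permutation test.

Replicated studies of power (leader-biased planting must be detected) and
type-I error (unbiased planting must be rejected at the nominal rate).
They draw planted targeting flags with the community generator's own
placement rule but skip sequence rendering, so thousands of replicates are
affordable; the test statistic sees exactly the same inputs it would
receive from a full pipeline run on a rendered community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SimulationConfig, sample_targeting_flags
from .stats import position_permutation_test
from .types import Cassette, Spacer


def _synthetic_cassettes(sizes: list[int]) -> list[Cassette]:
    """Oriented, complete cassette skeletons with the given spacer counts."""
    out = []
    for k, n in enumerate(sizes):
        cid = f"cal{k}"
        spacers = [
            Spacer(cassette_id=cid, serial=i + 1,
                   interval=(100 + i * 60, 130 + i * 60),
                   sequence="A" * 30, provisional=False)
            for i in range(n)
        ]
        out.append(Cassette(
            id=cid, contig_id=f"ctg{k}", interval=(0, 200 + n * 60),
            repeat_intervals=[(70, 100)], spacers=spacers,
            repeat_consensus="A" * 30, leader_end="left", complete=True,
        ))
    return out


@dataclass
class CalibrationResult:
    n_replicates: int
    n_rejected: int
    alpha: float

    @property
    def rejection_rate(self) -> float:
        return self.n_rejected / self.n_replicates


def position_test_rejection_rate(
    *,
    leader_bias: float,
    n_replicates: int,
    alpha: float,
    n_perm: int = 2000,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> CalibrationResult:
    """Fraction of replicate communities where the position test rejects.

    Each replicate draws cassette sizes and planted targeting flags under
    the study conditions (``config`` defaults to the generator defaults)
    and runs the lower-tail position test for targeting spacers.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.spacers_per_cassette_range
    rejected = 0
    for _ in range(n_replicates):
        sizes = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_cassettes)]
        flags = sample_targeting_flags(sizes, cfg.n_protospacers, leader_bias, rng)
        flagged = {(f"cal{c}", serial) for c, serial in flags}
        cassettes = _synthetic_cassettes(sizes)
        r = position_permutation_test(
            cassettes, flagged, n_perm=n_perm,
            seed=int(rng.integers(2**31)), tail="lower",
        )
        if r.p_value < alpha:
            rejected += 1
    return CalibrationResult(n_replicates=n_replicates, n_rejected=rejected, alpha=alpha)
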