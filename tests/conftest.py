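"""Shared fixtures: study topologies and the pooled synthetic benchmark."""

import numpy as np
import pytest
from hypothesis import settings

import phosdyn as P

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from phosdyn.pairs import PairSeries
from phosdyn.topology import enumerate_complementary_steps, study_topologies


@pytest.fixture(scope="session")
def oligo4():
    return P.build_topology("CGCACGTACGCG", "Oligo 4")


@pytest.fixture(scope="session")
def benchmark_pairs():
    """Pooled pair series over 36 independent synthetic complementary steps.

    The four study dodecamers, stationary BII probabilities spaced over
    0.05-0.8 assigned pairwise to the 72 phosphates, persistence 0.99,
    1e5 frames at 1 ps, independent facing dynamics; angles are emitted and
    classified at the 0-deg cutoff, so the classifier is part of the loop.
    """
    rng_seed = np.random.SeedSequence(0)
    kids = [int(c.generate_state(1)[0] % 2**31) for c in rng_seed.spawn(4)]
    g72 = np.linspace(0.05, 0.8, 72)
    all_ps = []
    k = 0
    for ti, topo in enumerate(study_topologies()):
        specs = {}
        for s1, s2 in enumerate_complementary_steps(topo):
            specs[(s1.strand, s1.pos5)] = P.StepDynamicsSpec(
                target_bii=(g72[2 * k], g72[2 * k + 1]), persistence=0.99
            )
            k += 1
        series, _ = P.simulate_backbone(
            topo, specs, P.EmissionSpec.pmd_defaults(), 100_000, seed=kids[ti]
        )
        states = P.classify_backbone_state(series, 0.0)
        all_ps.append(P.combine_states(states, topo))
    return PairSeries(
        steps=sum((p.steps for p in all_ps), []),
        codes=np.vstack([p.codes for p in all_ps]),
    )
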