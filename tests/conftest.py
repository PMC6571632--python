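import numpy as np
import pytest

import hipposim as h
from hipposim.microcircuit import CA1_PCS, CA3_PCS

N_SEED_PAIRS = 10
DURATION_MS = 10000.0


@pytest.fixture(scope="session")
def default_network():
    return h.build_default_network(seed=1)


@pytest.fixture(scope="session")
def paired_runs():
    """Ten seed-paired (control, pathology) 10 s runs of the default model.

    Shared across the behavioral tests because full-length runs dominate
    suite runtime.
    """
    pairs = []
    for seed in range(1, N_SEED_PAIRS + 1):
        net = h.build_default_network(seed=seed)
        control = h.run(net, DURATION_MS, seed=seed)
        schedule = h.build_lesion_schedule(net)
        pathology = h.run(net, DURATION_MS, seed=seed, lesion_schedule=schedule)
        pairs.append((control, pathology))
    return pairs


def region_pc_counts(result, region):
    pcs = CA1_PCS if region == "CA1" else CA3_PCS
    return [result.spike_count(c) for c in pcs]
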