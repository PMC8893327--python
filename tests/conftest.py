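"""Shared fixtures: one small synthetic study reused across the suite.

The session fixture set is a 200 kb single-chromosome genome with 3 TE
families and 20 IGEs, a 10-individual pooled sample carrying 20 fully
penetrant insertions, and its 20X error-free 75 bp paired library — small
enough to map in seconds, rich enough to exercise every pipeline stage.
"""

import pytest
from hypothesis import settings

from telscope.caller import call_insertions
from telscope.mapping import align_reads
from telscope.simulate import (
    SeqParams,
    build_reference,
    plant_insertions,
    random_insertion_plan,
    simulate_wgs,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    return build_reference(200_000, 1, 3, 20, seed=11)


@pytest.fixture(scope="session")
def penetrant_sample(bundle):
    plan = random_insertion_plan(bundle, 20, 1.0, seed=12, min_spacing=900)
    return plant_insertions(bundle, plan, 10, seed=13)


@pytest.fixture(scope="session")
def wgs_reads(penetrant_sample):
    reads, _truth = simulate_wgs(penetrant_sample, SeqParams(depth=20.0, seed=14))
    return reads


@pytest.fixture(scope="session")
def wgs_alns(wgs_reads, bundle):
    return align_reads(wgs_reads, bundle, mode="genome_split")


@pytest.fixture(scope="session")
def consensus_alns(wgs_reads, bundle):
    return align_reads(wgs_reads, bundle, mode="consensus_end_to_end")


@pytest.fixture(scope="session")
def landscape(wgs_alns, bundle):
    return call_insertions(wgs_alns, bundle, "fixture")
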