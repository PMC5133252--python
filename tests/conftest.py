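import numpy as np
import pytest

from bcelldev.types import Rearrangement


def make_read(
    read_id="r1",
    donor_id="D01",
    subset="preB",
    chain="IGH",
    v_call="IGHV3-23",
    d_call="IGHD3-10",
    j_call="IGHJ4",
    cdr3_nt="GCGAGAGATACG",
    cdr3_aa="ARDT",
    productive=True,
    **kw,
):
    if chain != "IGH":
        d_call = None
    return Rearrangement(
        read_id=read_id, donor_id=donor_id, subset=subset, chain=chain,
        v_call=v_call, d_call=d_call, j_call=j_call, cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa, productive=productive, **kw,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240001)


@pytest.fixture(scope="session")
def small_heavy_sim():
    """Small default-profile heavy-chain simulation shared across tests."""
    from bcelldev.simulate import SimulationConfig, simulate_repertoire

    cfg = SimulationConfig(n_donors=3, clonotypes_per_subset=400, seed=11)
    return simulate_repertoire(cfg, chain="IGH")
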