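import numpy as np
import pytest

import ddcnv
from ddcnv.sim import NtcConfig, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20220516)


@pytest.fixture
def normal_cn6_config():
    """A well at the normal triplicate state: CN 6, 3:1 target:reference."""
    return SimConfig(n_droplets=20000, lambda_ref=0.5, true_cn=6.0, seed=101)


@pytest.fixture
def small_plate():
    """Four sample wells at CN 6 plus one NTC, ready for the pipeline."""
    seeds = ddcnv.spawn_seeds(7, 5)
    configs = {
        f"A{i+1:02d}": SimConfig(n_droplets=15000, true_cn=6.0, seed=seeds[i])
        for i in range(4)
    }
    return ddcnv.simulate_plate(
        configs, include_ntc=True, ntc_config=NtcConfig(n_droplets=15000, seed=seeds[4])
    )


def make_run(
    sample="S1",
    assay="exon_VIII",
    experiment="E1",
    well="A01",
    n_pp=7000,
    n_pn=10000,
    n_np=1000,
    n_nn=2000,
    cn=6.0,
    acgh_cn=None,
    flags=(),
    status="pass",
):
    """Hand-built RunRecord with a consistent-looking quantification."""
    counts = ddcnv.ClusterCounts(n_pp=n_pp, n_pn=n_pn, n_np=n_np, n_nn=n_nn)
    quant = ddcnv.WellQuant(
        lambda_target=cn / 4.0,
        lambda_ref=0.5,
        ratio=cn / 2.0,
        cn_estimate=cn,
        ci_low=cn * 0.95,
        ci_high=cn * 1.05,
        n_total=counts.total,
        concentration_target=cn / 4.0 / 0.85e-3,
        concentration_ref=0.5 / 0.85e-3,
    )
    return ddcnv.RunRecord(
        sample_id=sample,
        assay_id=assay,
        experiment_id=experiment,
        well_id=well,
        counts=counts,
        quant=quant,
        exclusion_flags=frozenset(flags),
        acgh_cn=acgh_cn,
        qc_status=status,
    )
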