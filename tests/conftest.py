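import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cernet import pipeline, simulate
from cernet.cerna import CeRNANetwork, CeRNAPair

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study():
    """The default synthetic study: 4 planted hub lncRNAs, 10 vs 10 samples."""
    return simulate.simulate_study(simulate.SimConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_files(study, tmp_path_factory):
    """The same study written out in the on-disk TSV dialects."""
    outdir = tmp_path_factory.mktemp("study")
    return simulate.write_study(study, outdir)


@pytest.fixture(scope="session")
def run_config(study_files, tmp_path_factory):
    return pipeline.RunConfig(
        expression=study_files["expression"],
        groups=study_files["groups"],
        biotypes=study_files["biotypes"],
        lnc_mirna=study_files["lnc_mirna"],
        mirna_mrna=study_files["mirna_mrna"],
        outdir=str(tmp_path_factory.mktemp("run")),
    )


@pytest.fixture(scope="session")
def run_summary(run_config):
    """One full pipeline run on the study fixture, shared across tests."""
    return pipeline.run(run_config)


def make_network(edges, p_max=0.01, min_shared=3):
    """Build a CeRNANetwork from bare (lnc, mrna[, shared]) tuples for
    topology/subnetwork tests that do not care about the pair statistics."""
    pairs = []
    for e in edges:
        lnc, mrna = e[0], e[1]
        shared = tuple(sorted(e[2])) if len(e) > 2 else ()
        pairs.append(CeRNAPair(lnc=lnc, mrna=mrna, r=len(shared),
                               n=max(len(shared), 1), t=max(len(shared), 1),
                               m=100, shared=shared, p=0.001))
    pairs.sort(key=lambda e: (e.p, e.lnc, e.mrna))
    return CeRNANetwork(
        edges=tuple(pairs),
        lnc_nodes=tuple(sorted({e.lnc for e in pairs})),
        mrna_nodes=tuple(sorted({e.mrna for e in pairs})),
        p_max=p_max, min_shared=min_shared, n_scored=len(pairs),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
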