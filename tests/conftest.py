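import numpy as np
import pytest

import striatal_ensembles as se


@pytest.fixture(scope="session")
def small_experiment():
    """Four-condition smFISH experiment, 2 sections x 4000 cells each."""
    params = se.SectionSimParams(n_cells=4000, seed=7)
    design = [(c, 2) for c in ("control", "acute", "repeated", "challenge")]
    return se.simulate_experiment(design, params)


@pytest.fixture(scope="session")
def classified_cells(small_experiment):
    cells, _ = small_experiment
    thresholds = se.derive_thresholds(cells)
    return se.classify_cells(cells, thresholds), thresholds


@pytest.fixture(scope="session")
def hotspot_scenario_params():
    """Recruitment concentrated at the planted VLS hotspot, low MS background."""
    prob = {}
    for region in ("MS", "VLS"):
        for ctype in ("Drd1", "Drd2", "other"):
            prob[(region, "control", ctype)] = 0.10
            prob[(region, "acute", ctype)] = (
                0.08 if region == "MS" else (0.65 if ctype == "Drd1" else 0.10)
            )
    return se.SectionSimParams(n_cells=5000, recruit_prob=prob, seed=3)


@pytest.fixture(scope="session")
def bulk_planted():
    """200-gene bulk time course with 20 genes planted at fold 4."""
    params = se.BulkSimParams(n_genes=200, n_induced=20, seed=1)
    return se.simulate_counts(params)


@pytest.fixture(scope="session")
def bulk_planted_screen(bulk_planted):
    counts, meta, truth = bulk_planted
    return se.induction_lrt(counts, meta), counts, meta, truth


def pytest_configure(config):
    np.seterr(all="ignore")
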