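import numpy as np
import pandas as pd
import pytest

import prolncs as P


@pytest.fixture(scope="session")
def gene_sets():
    return P.generate_gene_sets(7, 50, 500, seed=1)


@pytest.fixture(scope="session")
def cohort(gene_sets):
    """Standard cohort with planted subtypes, modulators and hazards."""
    return P.generate_cohort(
        gene_sets, 200, subtype_shift=2.0, modulator_frac=0.2, n_lnc=60,
        hazard_beta=0.8, censor_rate=0.3, seed=3,
    )


@pytest.fixture(scope="session")
def activity(gene_sets, cohort):
    mrna, _, _, _ = cohort
    return P.score_gene_sets(mrna, gene_sets)


def random_survival(rng, n, lp=None, censor_frac=0.3):
    """Exponential survival helper used across test modules."""
    if lp is None:
        lp = np.zeros(n)
    t = rng.exponential(1.0, size=n) / (0.03 * np.exp(lp))
    if censor_frac > 0:
        c = rng.uniform(0, np.quantile(t, min(0.95, 1.5 * (1 - censor_frac))), size=n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
    else:
        time, event = t, np.ones(n, dtype=int)
    return P.SurvivalTable(
        pd.DataFrame(
            {"time": time + 1e-9, "event": event},
            index=[f"s{i:04d}" for i in range(n)],
        )
    )
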