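import numpy as np
import pandas as pd
import pytest

import klsconn as k


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-group cohort shared across tests that only need shapes."""
    spec = k.HumanCohortSpec(
        n_cases=4, n_controls=4, n_roi=6, voxels_per_roi=40, seed=11
    )
    subjects, design = k.generate_human_cohort(spec)
    return spec, subjects, design


@pytest.fixture(scope="session")
def probe_table():
    """Three-donor probe table with a stable and a noisy probe per gene."""
    rng = np.random.default_rng(5)
    regions = [f"R{i:02d}" for i in range(8)]
    donors = ["D01", "D02", "D03"]
    recs = []
    for gene in ["geneA", "geneB"]:
        profile = rng.normal(7, 1, len(regions))
        for probe, noise in [(f"{gene}_p1", 0.0), (f"{gene}_p2", 3.0)]:
            for donor in donors:
                vals = profile + rng.normal(0, noise, len(regions)) if noise else profile
                for reg, v in zip(regions, vals):
                    recs.append((probe, gene, donor, reg, v, 4.0))
    return pd.DataFrame(
        recs,
        columns=["probe_id", "gene_symbol", "donor_id", "region_id", "intensity", "background"],
    )
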