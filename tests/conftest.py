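import pandas as pd
import pytest

from soilrich.community import ASVTable
from soilrich.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = SimulationConfig(
        n_sites=60,
        species_pool_size=600,
        read_depth=3000,
        samples_per_site_range=(1, 3),
        seed=11,
    )
    return simulate_study(cfg)


def make_toy_table():
    """Five taxa, three samples; one archaeon, one global singleton."""
    counts = pd.DataFrame(
        {
            "s1": [10, 5, 0, 1, 20],
            "s2": [8, 0, 3, 0, 15],
            "s3": [12, 2, 5, 0, 30],
        },
        index=["t_bact1", "t_bact2", "t_bact3", "t_single", "t_arch"],
    )
    kingdom = pd.Series(
        ["Bacteria", "Bacteria", "Bacteria", "Bacteria", "Archaea"],
        index=counts.index,
    )
    meta = pd.DataFrame(
        {
            "site": ["A", "A", "B"],
            "lat": [10.01, 10.09, 10.11],
            "lon": [20.01, 20.09, 20.11],
        },
        index=counts.columns,
    )
    return ASVTable(counts=counts, kingdom=kingdom, sample_meta=meta)


@pytest.fixture()
def toy_table():
    return make_toy_table()


def site_richness(study):
    """Observed per-sample richness averaged within site, aligned to the
    covariate table of a synthetic study."""
    rich = (study.asv_table.counts > 0).sum(axis=0)
    per_site = rich.groupby(study.asv_table.sample_meta["site"]).mean()
    return per_site.loc[study.covariates.index].to_numpy(dtype=float)
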