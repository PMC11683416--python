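"""Shared fixtures: a small simulated dataset and its full analysis."""

from __future__ import annotations

import pytest

from dupmeth.pipeline import AnalysisInputs, run_full_analysis
from dupmeth.simulate import SimulationConfig, simulate_two_species


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_ancestral_genes=300)


@pytest.fixture(scope="session")
def dataset(default_config):
    return simulate_two_species(default_config)


@pytest.fixture(scope="session")
def analysis(dataset):
    return run_full_analysis(AnalysisInputs.from_dataset(dataset))


def colon_trio_pvalue(seed: int, daughter_delta: float, n_ancestral_genes: int = 800,
                      coverage_mean: float = 20.0, species: str = "speciesA"):
    """Simulate one two-species dataset and run the colon daughter-vs-parental
    promoter sign test; returns (p, n_non_tied_trios, n_many_to_one_groups).

    Single shared tissue, relocation-dominant duplication: the conditions
    under which GOC separates parental from daughter copies.
    """
    config = SimulationConfig(
        seed=seed,
        n_ancestral_genes=n_ancestral_genes,
        n_chromosomes=5,
        tissues_a=("colon",),
        tissues_b=("colon",),
        dup_rate=0.45,
        tandem_prob=0.15,
        daughter_delta=daughter_delta,
        coverage_mean_a=coverage_mean,
        coverage_mean_b=coverage_mean,
    )
    ds = simulate_two_species(config)
    results = run_full_analysis(AnalysisInputs.from_dataset(ds))
    st = results.sign_tests
    row = st[
        (st.species == species)
        & (st.tissue == "colon")
        & (st.metric == "promoter_meth")
        & (st.comparison == "daughter_vs_parental")
        & (st.variant == "all")
    ]
    cl = results.classification
    n_groups = (
        cl[(cl.species == species) & (cl.ortholog_class == "many2one")].gene_id.nunique() // 2
    )
    if row.empty:
        return None, 0, n_groups
    return float(row.p_one_tailed.iloc[0]), int(row.n.iloc[0]), n_groups
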