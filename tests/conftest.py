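import numpy as np
import pandas as pd
import pytest

import pdmeta as m


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with three mild planted effects."""
    cfg = m.CohortConfig(
        n_case=12, n_control=12, n_taxa=60, depth_mean=2e4,
        planted_taxa=((0, 2.0), (7, 2.0), (13, -2.0)), seed=42,
    )
    counts, metadata, truth = m.generate_taxon_profiles(cfg)
    return counts, metadata, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects: case and control columns are exchangeable."""
    cfg = m.CohortConfig(n_case=10, n_control=10, n_taxa=50, depth_mean=1e4, seed=7)
    return m.generate_taxon_profiles(cfg)


@pytest.fixture()
def lineage_matrix():
    """Tiny hand-built matrix with known lineages."""
    lin = {
        "sp1": m.TaxonomyLineage(
            "Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
            "Prevotellaceae", "Prevotella", "Prevotella copri", unit="sp1"),
        "sp2": m.TaxonomyLineage(
            "Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
            "Prevotellaceae", "Prevotella", "Prevotella stercorea", unit="sp2"),
        "sp3": m.TaxonomyLineage(
            "Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
            "Ruminococcaceae", "Faecalibacterium", "F. prausnitzii", unit="sp3"),
    }
    data = pd.DataFrame(
        {"s1": [3.0, 5.0, 2.0], "s2": [1.0, 0.0, 4.0]}, index=["sp1", "sp2", "sp3"]
    )
    return m.CountMatrix(data=data, lineages=lin)


def random_count_matrix(rng, n_features=12, n_samples=6, with_lineage=False):
    data = pd.DataFrame(
        rng.integers(0, 50, size=(n_features, n_samples)).astype(float),
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    lineages = {}
    if with_lineage:
        fams = ["FamA", "FamB", "FamC"]
        for i in range(n_features):
            fam = fams[i % 3]
            lineages[f"f{i}"] = m.TaxonomyLineage(
                "Bacteria", "PhyX", "ClsX", "OrdX", fam, f"Gen{i % 5}", f"Sp{i}", unit=f"f{i}"
            )
    return m.CountMatrix(data=data, lineages=lineages)
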