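import numpy as np
import pandas as pd
import pytest

from halotrait.core import (
    AbundanceMatrix,
    Dataset,
    FunctionCatalog,
    GeneAbundanceTensor,
    Mechanism,
    ReferenceSets,
    SampleSet,
    TaxonTable,
    default_catalog,
)
from halotrait.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def catalog() -> FunctionCatalog:
    return default_catalog()


def noiseless_synth_config(seed: int = 7) -> SynthConfig:
    return SynthConfig(
        class_counts={
            "bacteria": {"linear_pos": 10, "linear_neg": 10, "null": 10},
            "archaea": {"threshold_pos": 5, "threshold_neg": 5, "null": 5},
        },
        n_low_abundance=2,
        nb_dispersion=0.0,
        gene_noise_cv=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def noiseless_data():
    return generate_dataset(noiseless_synth_config())


@pytest.fixture(scope="session")
def noisy_data():
    return generate_dataset(SynthConfig(seed=42))


def make_tiny_dataset() -> Dataset:
    """2 samples, 3 taxa, 4 genes; hand-checkable numbers."""
    samples = SampleSet(sample_ids=("S1", "S2"), ec=np.array([1.0, 5.0]))
    taxa = TaxonTable(
        pd.DataFrame(
            {
                "taxon_id": ["T1", "T2", "T3"],
                "domain": ["bacteria", "bacteria", "archaea"],
                "phylum": ["Proteobacteria", "Proteobacteria", "Euryarchaeota"],
                "genus": pd.array(["Halomonas", "Bacillus", None], dtype="string"),
                "genome_size_mb": [3.5, 4.1, 2.2],
            }
        ).set_index("taxon_id")
    )
    abundance = AbundanceMatrix(
        pd.DataFrame(
            [[2.0, 4.0], [10.0, 6.0], [1.0, 3.0]],
            index=["T1", "T2", "T3"],
            columns=["S1", "S2"],
        )
    )
    genes = GeneAbundanceTensor(
        pd.DataFrame(
            {
                "taxon_id": ["T1", "T1", "T2", "T3"],
                "gene_id": ["K00001", "K00002", "K00001", "GH5"],
                "sample_id": ["S1", "S2", "S1", "S2"],
                "abundance": [4.0, 8.0, 20.0, 6.0],
            }
        )
    )
    catalog = FunctionCatalog(
        pathway_map={
            "K00001": ("Metabolism", "Energy metabolism", "pathway A"),
            "K00002": ("Metabolism", "Energy metabolism", "pathway B"),
            "K00003": ("Cellular Processes", "Transport", "pathway C"),
            "GH5": ("Metabolism", "Glycan metabolism", "CAZyme class GH"),
        },
        mechanisms=(
            Mechanism("na_extrusion", "salt_resistance", frozenset({"K00003"})),
            Mechanism("GH", "cazyme", frozenset({"GH5"})),
        ),
    )
    refs = ReferenceSets(
        salt_tolerant_genera=("Halo",),
        reference_genomes={"Euryarchaeota": (2.0, 2.5, 3.0)},
    )
    return Dataset(samples, taxa, abundance, genes, catalog, refs)


@pytest.fixture
def tiny_dataset() -> Dataset:
    return make_tiny_dataset()
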