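import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from drugseq.core import PlateGeometry, PlateMap, generate_barcode_set
from drugseq.count import CountMatrix
from drugseq.simulate import build_transcriptome
from drugseq.workflows import barnyard_purity_experiment

SMALL_GEOMETRY = PlateGeometry(4, 6)


@pytest.fixture(scope="session")
def tiny_transcriptome():
    return build_transcriptome(
        {"human": 20, "mouse": 20, "ERCC": 3}, mean_length=400, seed=11
    )


@pytest.fixture(scope="session")
def small_barcodes():
    return generate_barcode_set(24, length=8, min_hamming=3, seed=5, geometry=SMALL_GEOMETRY)


def run_small_barnyard(outdir, seed=3, **kwargs):
    """A 4x6 two-species pipeline run at reduced scale, rates configurable."""
    defaults = dict(
        geometry=SMALL_GEOMETRY,
        molecules_per_well=300,
        n_genes_per_species=60,
        n_ercc=5,
        cross_contamination_rate=0.0,
        base_error_rate=0.0,
        pcr_duplication_rate=0.0,
    )
    defaults.update(kwargs)
    return barnyard_purity_experiment(outdir, seed=seed, **defaults)


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory):
    """Zero-error, zero-contamination, zero-duplication small pipeline run."""
    return run_small_barnyard(tmp_path_factory.mktemp("clean_run"), seed=7)


def truth_triple_counts(truth: pd.DataFrame, by: str = "barcode_well") -> pd.Series:
    """Brute-force oracle: distinct (well, gene, UMI) triples per cell."""
    dedup = truth.drop_duplicates([by, "gene", "umi"])
    return dedup.groupby([by, "gene"]).size()


def matrix_cell_counts(matrix: CountMatrix) -> pd.Series:
    frame = matrix.to_dense_frame()
    stacked = frame.stack()
    return stacked[stacked > 0].astype(np.int64)


def make_count_matrix(dense: pd.DataFrame, species: dict[str, str] | str = "human") -> CountMatrix:
    """Wrap a dense wells x genes frame into a CountMatrix for QC/DE tests."""
    if isinstance(species, str):
        species_col = [species] * dense.shape[1]
    else:
        species_col = [species[g] for g in dense.columns]
    genes = pd.DataFrame(
        {"species": species_col}, index=pd.Index(dense.columns, name="gene_id")
    )
    genes["is_ercc"] = genes["species"].str.upper() == "ERCC"
    n = dense.shape[0]
    wells = pd.DataFrame(
        {
            "treatment": "none",
            "dose_um": np.nan,
            "replicate": range(1, n + 1),
            "species": "human",
            "cell_line": "U2OS",
        },
        index=pd.Index(dense.index, name="well"),
    )
    X = sp.csr_matrix(dense.to_numpy(dtype=np.int64))
    return CountMatrix(X, wells, genes)


def make_plate_map(wells, geometry=SMALL_GEOMETRY, **columns) -> PlateMap:
    n = len(wells)
    table = pd.DataFrame(
        {
            "treatment": columns.get("treatment", ["none"] * n),
            "dose_um": columns.get("dose_um", [np.nan] * n),
            "replicate": columns.get("replicate", list(range(1, n + 1))),
            "species": columns.get("species", ["human"] * n),
            "cell_line": columns.get("cell_line", ["U2OS"] * n),
        },
        index=pd.Index(wells, name="well"),
    )
    return PlateMap(table, geometry)
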