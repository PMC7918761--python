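import numpy as np
import pandas as pd
import pytest

from met1c import dmc as dmc_mod
from met1c import synthetic as syn
from met1c import annotation as annot


@pytest.fixture(scope="session")
def default_design():
    return syn.SyntheticDesign(seed=11)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory, default_design):
    """One generated default dataset shared across the session."""
    out = tmp_path_factory.mktemp("rrbs")
    truth = syn.generate(default_design, out)
    return out, truth


@pytest.fixture(scope="session")
def matrix(dataset):
    out, _ = dataset
    meta = pd.read_csv(out / "samples.tsv", sep="\t")
    paths = {s: out / f"{s}.cov" for s in meta["sample"]}
    return dmc_mod.read_coverage(paths, meta)


@pytest.fixture(scope="session")
def feature_index(dataset):
    out, _ = dataset
    return annot.build_index(out / "genes.gff3", out / "cpg_islands.bed")


@pytest.fixture(scope="session")
def icm_united(matrix, dataset):
    """United/filtered matrix for the ICM methionine contrast."""
    out, truth = dataset
    within = matrix.sample_mask(lineage="ICM")
    united = dmc_mod.unite_and_filter(
        matrix, mincov=5, variant_mask=out / "variants.bed",
        sample_mask=within, exclude_contigs=[truth.spikein_contig])
    return united.subset_samples(within)
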