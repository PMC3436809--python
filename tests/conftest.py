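"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest
from hypothesis import settings

import eqtlnet as eq

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def write(path, text: str) -> str:
    path.write_text(text)
    return str(path)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest spiked cohort used across modules (seeded, in-memory)."""
    cfg = eq.default_study_config(seed=42, n_patients=200, n_snps=60,
                                  n_genes=7, n_spiked_pairs=2,
                                  n_spiked_relevant=5)
    return eq.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset_files(small_dataset, tmp_path_factory):
    """The same cohort written to disk with PLINK-mirror result files."""
    out = tmp_path_factory.mktemp("dataset")
    paths = small_dataset.write(out)
    single, pairs = eq.generate_result_files(small_dataset, epi1=1e-4,
                                             out_dir=out)
    paths["single"] = out / "single_locus.tsv"
    paths["pairs"] = out / "two_locus.tsv"
    return small_dataset, paths
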