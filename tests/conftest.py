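"""Shared fixtures: all test data is generated programmatically at run time."""

from __future__ import annotations

import numpy as np
import pytest

from ldsim.fixtures import FixtureSpec, make_fixture
from ldsim.genetic_map import load_map
from ldsim.haplotype import HaplotypePool, fit_model
from ldsim.vcf_io import read_phased_vcf


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """100-variant AR-1 fixture with its truth manifest, VCF and map on disk."""
    out = tmp_path_factory.mktemp("fix")
    spec = FixtureSpec(n_variants=100, n_samples=1000, maf_range=(0.05, 0.5),
                       ld=("ar1", 0.8), seed=3)
    manifest = make_fixture(spec, out)
    return spec, manifest


@pytest.fixture(scope="session")
def small_haps(small_fixture):
    spec, manifest = small_fixture
    variants, haps = read_phased_vcf(manifest["vcf"])
    return variants, haps, manifest


@pytest.fixture(scope="session")
def small_model(small_haps):
    _, haps, _ = small_haps
    return fit_model(haps)


@pytest.fixture(scope="session")
def rare_fixture(tmp_path_factory):
    """30 variants with MAF in [0.02, 0.1] — the family-study genotype region."""
    out = tmp_path_factory.mktemp("rare")
    spec = FixtureSpec(n_variants=30, n_samples=600, maf_range=(0.02, 0.1), seed=7)
    manifest = make_fixture(spec, out)
    variants, haps = read_phased_vcf(manifest["vcf"])
    model = fit_model(haps)
    gmap = load_map(manifest["map"])
    cms = gmap.bp_to_cm(variants["pos"].to_numpy())
    return manifest, variants, model, np.asarray(cms, dtype=float)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
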