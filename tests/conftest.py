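"""Shared fixtures: synthetic genomes, kernels and landscapes.

Expensive objects (DDFE kernels, the standard 1-Mb genome and its default B
landscape) are session-scoped so the full suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bgsmap.annotation import classify_sites, count_selected_sites
from bgsmap.bgs import build_kernel, compute_B
from bgsmap.models import parse_model_id
from bgsmap.recmap import read_recmap
from bgsmap.simulate import SyntheticSpec, generate_genome

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def _load_genome(spec: SyntheticSpec, outdir):
    files = generate_genome(spec, outdir)
    recmap = read_recmap(files.recmap_tsv)
    labels = classify_sites(
        files.gff3,
        files.te_bed,
        chromosome=spec.chromosome,
        chromosome_length=spec.chromosome_length,
    )
    track = count_selected_sites(labels, chromosome=spec.chromosome)
    return {
        "spec": spec,
        "files": files,
        "recmap": recmap,
        "labels": labels,
        "track": track,
    }


@pytest.fixture(scope="session")
def toy100kb(tmp_path_factory):
    """100-kb chromosome with 10 genes: the oracle-comparison fixture."""
    spec = SyntheticSpec(seed=1, chromosome_length=100_000, n_genes=10)
    return _load_genome(spec, tmp_path_factory.mktemp("toy100kb"))


@pytest.fixture(scope="session")
def std_genome(tmp_path_factory):
    """The standard 1-Mb synthetic genome (100 genes, chromosome-like map)."""
    spec = SyntheticSpec(seed=1)
    return _load_genome(spec, tmp_path_factory.mktemp("std_genome"))


@pytest.fixture(scope="session")
def default_model():
    return parse_model_id("M_LN,StdMut,CO+GC")


@pytest.fixture(scope="session")
def kernel_cache(default_model):
    """One kernel per DDFE family at the autosomal threshold, built once."""
    thr = default_model.threshold()
    gamma_model = parse_model_id("M_G,StdMut,CO+GC")
    return {
        "LN": build_kernel(default_model.ddfe_aa, thr),
        "G": build_kernel(gamma_model.ddfe_aa, thr),
    }


@pytest.fixture(scope="session")
def default_landscape(std_genome, default_model, kernel_cache):
    return compute_B(
        std_genome["track"],
        std_genome["recmap"],
        kernel_cache["LN"],
        default_model.rates_by_class(),
        include_gc=True,
        model_id=default_model.model_id,
    )
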