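"""Shared fixtures: small synthetic datasets and record factories."""

from __future__ import annotations

import numpy as np
import pytest

from pseudopan.records import PseudogeneRecord
from pseudopan.simulate import SimConfig, simulate_dataset


def make_record(uid="r1", strain="A", chrom="chr1", start=1000, end=2000, strand="+",
                biotype="processed", parent="g1", identity=90.0, coverage=0.8,
                source="auto", **kw):
    return PseudogeneRecord(uid=uid, strain_id=strain, chrom=chrom, start=start,
                            end=end, strand=strand, biotype=biotype, parent_id=parent,
                            pct_identity=identity, query_coverage=coverage,
                            source=source, **kw)


@pytest.fixture
def mk_rec():
    return make_record


@pytest.fixture(scope="session")
def slim_dataset():
    """Small default-noise dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=11, n_genes=250,
                                      expected_pseudogenes_per_strain=600))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free channels and liftovers: truth is directly recoverable."""
    cfg = SimConfig(seed=19, n_genes=200, expected_pseudogenes_per_strain=500,
                    auto_fp_rate=0.0, auto_fn_rate=0.0, manual_dropout=0.0,
                    liftover_gap_fraction=0.0, detection_decay=0.0,
                    assembly_quality=1.0, boundary_jitter_bp=0,
                    truncation_prob=0.0)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
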