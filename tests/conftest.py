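"""Shared fixtures: one session-scoped synthetic holobiont dataset and the
annotation chain (ORFs, peptides, reference hits) derived from it."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from holotx import homology, orffinder, simulate

HOLO_SEED = 11


@pytest.fixture(scope="session")
def holo():
    """Synthetic holobiont study at the default desk-scale conditions."""
    truth, m1, m2 = simulate.simulate_holobiont(seed=HOLO_SEED, n_pairs=2000)
    return truth, m1, m2


@pytest.fixture(scope="session")
def annotated(holo):
    """ORFs from the true transcripts plus their reference-proteome hits at
    the 2e-30 annotation threshold."""
    truth, _, _ = holo
    orfs = []
    for t in truth.transcripts:
        orfs.extend(orffinder.find_orfs(t, 150))
    peptides = orffinder.orf_peptides(orfs)
    hits = homology.search(peptides, truth.reference_proteome,
                           homology.PROTEIN_SCHEME, evalue_max=2e-30)
    return orfs, peptides, hits


SMALL_PIPELINE_CONFIG = {
    "simulate": {
        "n_families": 6,
        "paralogs_per_family": 2,
        "n_host": 16,
        "n_symbiont": 4,
        "n_pairs": 1200,
        "length_range": [100, 160],
        "host_divergence": 0.05,
        "symbiont_pool_divergence": 0.50,
        "error_rate": 0.0,
        "read_len": 75,
        "insert_mean": 180,
        "insert_sd": 25,
        "expression_sigma": 0.6,
    },
    "assembly": {"k_values": [29, 35, 41], "min_kmer_count": 1},
}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One small end-to-end pipeline run shared by report-shape tests."""
    from holotx.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipe")
    report = run_pipeline(SMALL_PIPELINE_CONFIG, seed=5, out_dir=out)
    return report, out
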