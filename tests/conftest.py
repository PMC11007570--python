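"""Shared fixtures.

The expensive benchmark community (full study conditions: 5 Mb host at
30x, three prey mitogenomes at 40-100x, a fourth at 0.5x) is built once
per session and shared by the acceptance tests that measure recovery.
"""

from __future__ import annotations

import pytest

from mitofish.pipeline import RunConfig, run_pipeline
from mitofish.simulate import build_panel_genome


@pytest.fixture(scope="session")
def small_genome():
    """One deterministic prey mitogenome with the default architecture."""
    return build_panel_genome(seed=11, genome_id="mtg")


@pytest.fixture(scope="session")
def standard_run(tmp_path_factory):
    """Full pipeline on the benchmark community (fixed seed)."""
    outdir = tmp_path_factory.mktemp("standard_run")
    config = RunConfig(outdir=str(outdir), seed=1)
    report = run_pipeline(config)
    return config, report
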