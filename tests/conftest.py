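"""Shared fixtures: small synthetic triads generated once per session."""

import logging

import pytest

from reducta.pipeline import analyze_triad
from reducta.synthsim import SimConfig, simulate_triad

logging.getLogger("reducta").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_triad():
    """A 60-gene triad at the default study conditions, with its manifest."""
    cfg = SimConfig(seed=42, n_genes=60, n_rna=6)
    genomes, manifest = simulate_triad(cfg)
    return cfg, genomes, manifest


@pytest.fixture(scope="session")
def small_triad_result(small_triad):
    cfg, genomes, manifest = small_triad
    return analyze_triad(genomes, cfg.tree, seed=1, hotspot_nperm=999)


def truth_event_counter(manifest):
    from collections import Counter

    truth = Counter()
    for d in manifest["families"].values():
        for e in d["events"]:
            truth[(e["branch"], e["event"])] += 1
    return truth


def detected_event_counter(result):
    from collections import Counter

    det = Counter()
    for r in result.events.rows:
        det[(r.branch_id, r.event)] += 1
    return det
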