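"""Shared fixtures."""

from __future__ import annotations

import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def small_genome():
    rng = random.Random(42)
    return "".join(rng.choice("ACGT") for _ in range(3000))


@pytest.fixture(scope="session")
def small_graph(small_genome):
    from hybridec.graph_core import build_graph

    return build_graph([small_genome], 9, 1)
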