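import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from stromacomp.go_dag import GoDag, GoTerm, propagate_annotations


@pytest.fixture
def chain_dag() -> GoDag:
    """root <- A <- A1 linear chain."""
    return GoDag([
        GoTerm("root", "bp root", "biological_process", {}),
        GoTerm("A", "term A", "biological_process", {"root": "is_a"}),
        GoTerm("A1", "term A1", "biological_process", {"A": "is_a"}),
    ])


@pytest.fixture
def diamond_dag() -> GoDag:
    """A -> {B, C} -> D diamond."""
    return GoDag([
        GoTerm("D", "top", "biological_process", {}),
        GoTerm("B", "left", "biological_process", {"D": "is_a"}),
        GoTerm("C", "right", "biological_process", {"D": "part_of"}),
        GoTerm("A", "bottom", "biological_process", {"B": "is_a", "C": "is_a"}),
    ])


@pytest.fixture
def worked_enrichment(chain_dag):
    """The hand-built conditional-enrichment fixture: 20-gene universe,
    A1 = {g1..g5}, A additionally {g6..g8}, foreground {g1..g4, g10}."""
    direct = {f"g{i}": {"A1"} for i in range(1, 6)}
    direct.update({f"g{i}": {"A"} for i in range(6, 9)})
    direct.update({f"g{i}": {"root"} for i in range(9, 21)})
    ann = propagate_annotations(chain_dag, direct)
    universe = {f"g{i}" for i in range(1, 21)}
    foreground = {"g1", "g2", "g3", "g4", "g10"}
    return chain_dag, ann, universe, foreground
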