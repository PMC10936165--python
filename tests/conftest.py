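import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from genoslim.annotation import GeneFeature, GenomeAnnotation
from genoslim.homology import EssentialityMap
from genoslim.models import ModelDocument, Reaction


@pytest.fixture
def toy1_model() -> ModelDocument:
    """Three-reaction closed-form model: uptake (ub 10) -> conversion
    (gated by gA) -> biomass consuming 10 P, so mu_max = 1.0."""
    return ModelDocument(
        "TOY1",
        {"C": "c", "P": "c"},
        [
            Reaction("R_up", {"C": 1.0}, 0.0, 10.0, ""),
            Reaction("R_conv", {"C": -1.0, "P": 1.0}, 0.0, 1000.0, "gA"),
            Reaction("R_bio", {"P": -10.0}, 0.0, 1000.0, ""),
        ],
        "R_bio",
    )


@pytest.fixture
def six_gene_setup():
    """Hand-built 6-gene genome: g1, g4, g6 essential; all dispensable
    windows growth-neutral.  Genes are 1 kb, abutting, plus strand."""
    features = [
        GeneFeature(f"g{i + 1}", i * 1000, (i + 1) * 1000, "+", protein="M" + "A" * 49)
        for i in range(6)
    ]
    ann = GenomeAnnotation("toychr", 6000, features)
    labels = {
        "g1": "essential",
        "g2": "dispensable",
        "g3": "dispensable",
        "g4": "essential",
        "g5": "dispensable",
        "g6": "essential",
    }
    ess = EssentialityMap(labels, {l: None for l in labels})
    model = ModelDocument(
        "toy6",
        {"C": "c", "P": "c", "X1": "c", "X4": "c", "X6": "c"},
        [
            Reaction("R_uptake", {"C": 1.0}, 0.0, 10.0, ""),
            Reaction("R_main", {"C": -1.0, "P": 1.0}, 0.0, 1000.0, ""),
            Reaction("R_e1", {"C": -1.0, "X1": 1.0}, 0.0, 1000.0, "g1"),
            Reaction("R_e4", {"C": -1.0, "X4": 1.0}, 0.0, 1000.0, "g4"),
            Reaction("R_e6", {"C": -1.0, "X6": 1.0}, 0.0, 1000.0, "g6"),
            Reaction(
                "R_bio",
                {"P": -7.0, "X1": -1.0, "X4": -1.0, "X6": -1.0},
                0.0,
                1000.0,
                "",
            ),
        ],
        "R_bio",
    )
    return ann, ess, model
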