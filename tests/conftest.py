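import numpy as np
import pytest

from synergyshot import (
    BackboneSpec,
    LabeledExample,
    SynergyRecord,
    WordTokenizer,
    label_records,
)
from synergyshot.lm_classifier import LmClassifier, TinyCausalLM
from synergyshot.synthetic_data import SyntheticConfig, TissueSpec, generate


@pytest.fixture
def worked_record() -> SynergyRecord:
    """The screen row used throughout the docs as the worked example."""
    return SynergyRecord(
        drug1_name="AZD1775",
        drug2_name="AZACITIDINE",
        cell_line_name="SF-295",
        tissue_name="bone",
        sensitivity1=0.568,
        sensitivity2=28.871,
        loewe_score=12.3,
        raw_text={
            "drug1": "AZD1775",
            "drug2": "AZACITIDINE",
            "cell_line": "SF-295",
            "tissue": "bone",
            "sensitivity1": "0.568",
            "sensitivity2": "28.871",
            "loewe_score": "12.3",
        },
    )


def make_examples(n: int, prevalence: float, seed: int = 0, tissue: str = "bone") -> list[LabeledExample]:
    """Labelled examples with an exact positive count (round(prevalence * n))."""
    rng = np.random.default_rng(seed)
    n_pos = int(round(prevalence * n))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1
    records = [
        SynergyRecord(
            drug1_name=f"d{rng.integers(20):02d}",
            drug2_name=f"d{20 + rng.integers(20):02d}",
            cell_line_name=f"{tissue}-c{rng.integers(5)}",
            tissue_name=tissue,
            sensitivity1=float(np.round(rng.uniform(0, 100), 3)),
            sensitivity2=float(np.round(rng.uniform(0, 100), 3)),
            loewe_score=20.0 if labels[i] else -10.0,
        )
        for i in range(n)
    ]
    return label_records(records)


@pytest.fixture
def tiny_lm() -> LmClassifier:
    """A very small untrained classifier over a fixed toy vocabulary."""
    tok = WordTokenizer.fit(["alpha beta gamma delta one two three Positive Not positive Synergy :"])
    spec = BackboneSpec(layer_count=2, hidden_size=16, head_count=2, max_length=32)
    return LmClassifier(TinyCausalLM(spec, tok, seed=7), seed=7)


@pytest.fixture(scope="session")
def smoke_data():
    cfg = SyntheticConfig(
        n_drugs=16,
        n_mechanism_classes=2,
        tissues=[
            TissueSpec("lung", 6, 600, "common"),
            TissueSpec("bone", 3, 150, "rare"),
        ],
        seed=5,
    )
    return generate(cfg)
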