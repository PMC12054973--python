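import numpy as np
import pytest

from funcmatch.data_io import AnnotationDataset, FunctionTerm, ProteinRecord
from funcmatch.model_core import ModelConfig, build_model
from funcmatch.synthetic_data import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world (seed 7): train/val/test/zero-shot + motif map."""
    return generate_world(WorldConfig())


@pytest.fixture(scope="session")
def tiny_world_cfg():
    return WorldConfig(
        n_motifs=4,
        n_terms=10,
        n_sequences=30,
        n_val_sequences=10,
        n_test_sequences=10,
        n_zero_shot_sequences=10,
        frac_zero_shot_terms=0.2,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_world_cfg):
    return generate_world(tiny_world_cfg)


@pytest.fixture
def small_model():
    """An untrained pair scorer with toy dimensions."""
    return build_model(ModelConfig(d=8, seed=0), seq_dim=16, text_dim=12)


@pytest.fixture
def diamond_terms():
    """DAG: D -> {B, C}, B -> A, C -> A (child -> parent edges)."""
    return {
        "A": FunctionTerm("A", "molecular_function", "root activity"),
        "B": FunctionTerm("B", "molecular_function", "left branch", parents={"A"}),
        "C": FunctionTerm("C", "molecular_function", "right branch", parents={"A"}),
        "D": FunctionTerm("D", "molecular_function", "specific leaf", parents={"B", "C"}),
    }


def make_dataset(annotations: dict[str, set[str]], terms: dict[str, FunctionTerm],
                 split: str = "train") -> AnnotationDataset:
    """Dataset with fixed dummy sequences, one protein per annotation entry."""
    rng = np.random.default_rng(0)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    proteins = [
        ProteinRecord(sid, "".join(rng.choice(letters, size=30)), set(terms_for))
        for sid, terms_for in annotations.items()
    ]
    return AnnotationDataset(proteins, terms, split)
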