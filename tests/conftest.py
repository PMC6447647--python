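import numpy as np
import pytest

from selacq import (
    BehaviorDataset,
    GeneratorConfig,
    SimParams,
    SubjectRecord,
    ToyEmbeddingSpec,
    generate_dataset,
    generate_toy_embedding,
)


@pytest.fixture
def small_params() -> SimParams:
    """A 40E/10I network that steps fast."""
    return SimParams(n_ex=40, n_inh=10, seed=0)


@pytest.fixture(scope="session")
def toy_embedding():
    return generate_toy_embedding(ToyEmbeddingSpec(seed=11))


@pytest.fixture
def null_exp1_dataset() -> BehaviorDataset:
    """Lengths independent of confidence: the null of the confidence-length tests."""
    return generate_dataset(
        GeneratorConfig(n_subjects=30, n_forced=0, length_effect=0.0, seed=42)
    )


@pytest.fixture
def planted_exp1_dataset() -> BehaviorDataset:
    return generate_dataset(
        GeneratorConfig(n_subjects=30, n_forced=0, length_effect=1.0, seed=42)
    )


@pytest.fixture
def planted_exp2_dataset() -> BehaviorDataset:
    """Forced words get inflated confidence but no length advantage."""
    return generate_dataset(
        GeneratorConfig(
            n_subjects=30, n_forced=2, forced_conf_boost=25.0,
            length_effect=1.0, seed=7,
        )
    )


def make_subject(subject_id, confidence, essay_len, condition=None, tokens=None):
    n = len(confidence)
    return SubjectRecord(
        subject_id=subject_id,
        words=[f"w{k:02d}" for k in range(n)],
        condition=list(condition) if condition is not None else ["spontaneous"] * n,
        confidence=np.asarray(confidence, dtype=float),
        essay_len=np.asarray(essay_len, dtype=float),
        essay_tokens=tokens,
    )
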