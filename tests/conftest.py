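import numpy as np
import pytest

from himpairs import ExpressionMatrix, PairedDesign, PipelineConfig


def paired_design(n_patients: int) -> PairedDesign:
    samples, patients, status = [], [], []
    for i in range(n_patients):
        p = f"P{i + 1:03d}"
        for suffix, y in (("T", 1), ("N", 0)):
            samples.append(f"{p}_{suffix}")
            patients.append(p)
            status.append(y)
    return PairedDesign(samples, patients, np.array(status))


@pytest.fixture
def design10() -> PairedDesign:
    return paired_design(10)


@pytest.fixture
def counts10(design10) -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    vals = rng.poisson(50, size=(8, design10.n_samples)).astype(float)
    return ExpressionMatrix(vals, [f"g{i}" for i in range(8)],
                            design10.sample_ids, "mRNA", scale="raw")


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig(seed=1, cv_folds=5)
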