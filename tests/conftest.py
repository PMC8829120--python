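import numpy as np
import pandas as pd
import pytest

from mimrda import PRESET, run_pipeline, simulate_dataset
from mimrda.io_formats import ExpressionMatrix, SampleMetadata


@pytest.fixture(scope="session")
def preset_study():
    """One deterministic preset-scale study with planted disease miRNAs."""
    mrna, mirna, meta, inter, truth = simulate_dataset(PRESET, seed=1)
    return {"mrna": mrna, "mirna": mirna, "meta": meta,
            "interactions": inter, "truth": truth}


@pytest.fixture(scope="session")
def preset_scores(preset_study):
    """Pipeline output on the preset study."""
    scores, report = run_pipeline(
        preset_study["mrna"], preset_study["mirna"], preset_study["meta"],
        preset_study["interactions"])
    return {"scores": scores, "report": report}


@pytest.fixture
def tiny_expr():
    """2x4 expression matrix with an obvious group difference."""
    data = pd.DataFrame(
        [[2.0, 2.0, 1.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        index=["g1", "g2"], columns=["t1", "t2", "n1", "n2"])
    return ExpressionMatrix(data=data, feature_kind="mRNA")


@pytest.fixture
def tiny_meta():
    return SampleMetadata(table=pd.DataFrame(
        {"group": ["tumor", "tumor", "normal", "normal"]},
        index=pd.Index(["t1", "t2", "n1", "n2"], name="sample_id")))


def make_two_group_meta(n1: int, n2: int) -> SampleMetadata:
    samples = [f"T{i}" for i in range(n1)] + [f"N{i}" for i in range(n2)]
    return SampleMetadata(table=pd.DataFrame(
        {"group": ["tumor"] * n1 + ["normal"] * n2},
        index=pd.Index(samples, name="sample_id")))


def make_expr(values: np.ndarray, meta: SampleMetadata,
              kind: str = "mRNA") -> ExpressionMatrix:
    features = [f"f{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=features, columns=meta.sample_ids),
        feature_kind=kind)
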