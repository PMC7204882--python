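import numpy as np
import pandas as pd
import pytest

from traceorigin.datamodel import DEFAULT_ELEMENTS, ElementPanel, SampleTable
from traceorigin.preprocess import apply_scaler, fit_scaler, normalize_to_calcium
from traceorigin.synthetic import SynthConfig, generate_library


@pytest.fixture(scope="session")
def panel() -> ElementPanel:
    return ElementPanel()


def make_sample_table(conc: np.ndarray, panel: ElementPanel,
                      sites=None, **meta_overrides) -> SampleTable:
    """Build a valid SampleTable from a (n, 21) concentration array."""
    n = len(conc)
    df = pd.DataFrame(conc, columns=list(panel.elements))
    df["bird_id"] = [f"b{i}" for i in range(n)]
    df["site"] = sites if sites is not None else "S1"
    df["age_class"] = meta_overrides.get("age_class", "juvenile")
    df["season"] = meta_overrides.get("season", "summer")
    df["context"] = meta_overrides.get("context", "library")
    return SampleTable(df, panel)


@pytest.fixture(scope="session")
def default_library():
    """Default 10-site synthetic juvenile library (105 birds), seed 1."""
    return generate_library(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_zmatrix(default_library):
    ratio = normalize_to_calcium(default_library)
    return apply_scaler(fit_scaler(ratio), ratio)


def three_site_zmatrix(separation_sd: float, n_per: int = 20, p: int = 6,
                       seed: int = 0):
    """Three spherical groups spaced ``separation_sd`` SDs apart along the
    first axis; returns (DataFrame, labels)."""
    rng = np.random.default_rng(seed)
    means = np.zeros((3, p))
    means[:, 0] = np.arange(3) * separation_sd
    X = np.vstack([rng.normal(means[g], 1.0, size=(n_per, p))
                   for g in range(3)])
    labels = np.repeat([f"G{g}" for g in range(3)], n_per)
    cols = [f"v{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), labels
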