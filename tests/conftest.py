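import numpy as np
import pytest

from ppsw.synth import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vignetted_scene():
    """One 16-bit scene with a 0.5-strength vignette and all artifacts."""
    return generate_scene(SceneConfig(vignette_strength=0.5, seed=7))


@pytest.fixture(scope="session")
def flat_scene():
    """Background-only scene: no vignette, no artifacts, no blobs."""
    return generate_scene(
        SceneConfig(vignette_strength=0.0, artifact_set=(), blob_amplitude=0.0, seed=7)
    )


def make_informative_table(n=300, n_features=10, n_classes=3, seed=0, n_informative=2):
    """Feature table where only the first ``n_informative`` columns carry signal."""
    import pandas as pd

    r = np.random.default_rng(seed)
    x = r.random((n, n_features))
    score = x[:, :n_informative].sum(axis=1)
    edges = np.quantile(score, np.linspace(0, 1, n_classes + 1)[1:-1])
    y = np.digitize(score, edges)
    table = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_features)])
    table["density_label"] = [f"c{k}" for k in y]
    return table
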