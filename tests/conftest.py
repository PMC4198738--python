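import numpy as np
import pytest

import snpauth as sa


@pytest.fixture(scope="session")
def small_panel() -> sa.Database:
    """A compact but fully featured reference panel: 8 inbred strains (two
    replicates each), one substrain pair separated by 5 private differences,
    and two outbred lines with 3 individuals each, over 600 markers."""
    spec = sa.PanelSpec(
        n_strains=8,
        n_markers=600,
        n_replicates=2,
        substrain_pairs=[("S01", 5)],
        n_outbred_lines=2,
        samples_per_outbred=3,
        seed=11,
    )
    return sa.make_reference_panel(spec)


@pytest.fixture(scope="session")
def small_assay(small_panel) -> sa.AssayDefinition:
    return sa.select_assay_markers(small_panel)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(202_409)


def random_strain_pair(n_markers: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two unrelated homozygous strains over shared marker frequencies."""
    r = np.random.default_rng(seed)
    freqs = r.uniform(0.1, 0.5, n_markers)
    host = (r.random(n_markers) < freqs).astype(np.float32) * 2
    cont = (r.random(n_markers) < freqs).astype(np.float32) * 2
    return host, cont
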