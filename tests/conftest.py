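import numpy as np
import pytest

import cystfuse as cf


@pytest.fixture(scope="session")
def fast_config():
    """A small, explicitly spaced phantom configuration for quick unit tests."""
    return cf.PhantomConfig(
        grid_dims=(68, 68, 27), spacing_mm=(1.2, 1.2, 3.0), seed=0
    )


@pytest.fixture(scope="session")
def clean_config(fast_config):
    """Noise-free, misalignment-free variant for geometric invariants."""
    import dataclasses

    return dataclasses.replace(fast_config, noise_sd=0.0, bias_amplitude=0.0)


def make_separable_packs(n_per_class=20, delta=0.3, noise=0.05, seed=0):
    """Labeled slice packs where class separates on mean slice intensity.

    MCN slices sit at +delta, SCN at -delta, plus pixel noise; linearly
    separable from per-modality mean intensities.
    """
    rng = np.random.default_rng(seed)
    packs = []
    for i in range(2 * n_per_class):
        label = "MCN" if i < n_per_class else "SCN"
        base = delta if label == "MCN" else -delta
        slices = base + noise * rng.standard_normal((7, 80, 80))
        packs.append(
            cf.SlicePack(
                patient_id=f"S{i:03d}", z_index=40,
                slices=np.clip(slices, -1, 1).astype(np.float32), label=label,
            )
        )
    return packs


@pytest.fixture(scope="session")
def separable_packs():
    return make_separable_packs()
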