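import numpy as np
import pytest

from numsense import hcnn, stimuli


@pytest.fixture(scope="session")
def tiny_net():
    """A reduced network (same role sequence as the full architecture)."""
    return hcnn.build_network(hcnn.tiny_config(input_size=64, n_classes=10), seed=0)


@pytest.fixture(scope="session")
def tiny_manifest():
    """Balanced stimulus batch matched to the tiny network's input size."""
    return stimuli.generate_manifest(
        numerosities=(0, 1, 2),
        sets=("standard", "control2"),
        n_total=36,
        rng_seed=5,
        image_size=64,
    )


def synthetic_activation_matrix(
    n_units,
    manifest_table,
    tuned_units=None,
    noise_sd=0.2,
    seed=0,
    baseline=1.0,
):
    """Planted-code activation matrix for screening tests.

    ``tuned_units`` maps unit index -> (preferred numerosity, tuning width);
    tuned units respond with a Gaussian bump over numerosity plus noise, all
    others are pure noise around the baseline.
    """
    rng = np.random.default_rng(seed)
    nums = manifest_table["numerosity"].to_numpy()
    n_obs = len(nums)
    X = baseline + noise_sd * rng.standard_normal((n_units, n_obs))
    if tuned_units:
        for uid, (pref, width) in tuned_units.items():
            X[uid] += 2.0 * np.exp(-0.5 * ((nums - pref) / width) ** 2)
    return np.maximum(X, 0.0)


@pytest.fixture
def planted_code():
    return synthetic_activation_matrix
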