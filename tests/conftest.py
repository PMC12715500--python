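import numpy as np
import pytest

from pchscaffold import synthio

MIX = {
    "pericentric_heterochromatin": 0.10,
    "euchromatin": 0.05,
    "nucleolus": 0.05,
    "histone_deacetylase": 0.05,
    "histone_acetylase": 0.05,
    "nurd": 0.04,
}


@pytest.fixture(scope="session")
def annotations():
    return synthio.gen_annotations(300, MIX, seed=11)


@pytest.fixture(scope="session")
def dia_matrix(annotations):
    effects = {
        ("pericentric_heterochromatin", "HC_P"): 2.0,
        ("histone_acetylase", "HC_MBD2_P"): -6.0,
    }
    return synthio.gen_dia_experiment(
        annotations,
        [("HC", 3), ("HC_S", 3), ("HC_P", 3), ("HC_MBD2_P", 3)],
        params={"enrichment_effects": effects},
        seed=12,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down pipeline configuration for fast end-to-end runs."""
    return {
        "simulate": {
            "n_proteins": 150,
            "n_planted_scaffolds": 15,
            "n_published": 5,
            "image": {"shape": [64, 64], "n_foci": 3, "focus_radius": 4.0,
                      "focus_contrast": 6.0, "noise_sd": 1.0,
                      "n_images": 2},
            "image_3d": {"shape": [10, 48, 48], "n_foci": 3,
                         "focus_radius": 3.0, "focus_contrast": 6.0,
                         "noise_sd": 1.0},
            "frap": {"k_intra": 0.5, "k_boundary_condition": 0.02,
                     "k_boundary_control": 5.0, "bleach_depth": 0.8,
                     "noise_sd": 0.01, "n_pre": 9, "n_post": 60,
                     "dt": 1.3, "n_traces": 4},
        },
        "screen": {"top_n": 40, "self_cut": 40, "partner_cut": 40},
    }
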