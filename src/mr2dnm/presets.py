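"""Per-dataset hyperparameter presets for the five UCI benchmarks.

Each preset carries the synaptic steepness k, soma steepness and threshold,
branch count M, learning rate eta and epoch count used for that dataset,
plus its pre-cleaning feature/sample characteristics, so a full-scale
reproduction needs only the downloaded data file and a preset name.
"""

from __future__ import annotations

PRESETS: dict[str, dict] = {
    "wbcd": {
        "k": 1.0, "k_soma": 10.0, "theta_soma": 0.5,
        "n_branches": 45, "eta": 0.01, "iterations": 1000,
        "n_features": 9, "n_samples_clean": 683, "nominal": True,
    },
    "bupa": {
        "k": 3.0, "k_soma": 10.0, "theta_soma": 0.5,
        "n_branches": 10, "eta": 0.005, "iterations": 2000,
        "n_features": 7, "n_samples_clean": 345, "nominal": False,
    },
    "iono": {
        "k": 3.0, "k_soma": 10.0, "theta_soma": 0.5,
        "n_branches": 34, "eta": 0.001, "iterations": 1000,
        "n_features": 34, "n_samples_clean": 351, "nominal": False,
    },
    "pima": {
        "k": 3.0, "k_soma": 10.0, "theta_soma": 0.5,
        "n_branches": 25, "eta": 0.001, "iterations": 1000,
        "n_features": 8, "n_samples_clean": 768, "nominal": False,
    },
    "vote": {
        "k": 3.0, "k_soma": 10.0, "theta_soma": 0.5,
        "n_branches": 30, "eta": 0.001, "iterations": 1000,
        "n_features": 16, "n_samples_clean": 232, "nominal": True,
    },
}

#: Expected 70/30 train/test counts for each preset's cleaned sample size.
EXPECTED_SPLITS: dict[str, tuple[int, int]] = {
    "wbcd": (478, 205),
    "bupa": (242, 103),
    "iono": (246, 105),
    "pima": (538, 230),
    "vote": (162, 70),
}


def get_preset(name: str) -> dict:
    try:
        return dict(PRESETS[name.lower()])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def feature_reduction_percent(n_features: int, n_selected: int) -> float:
    """Percentage of original features removed by selecting n_selected."""
    if not 0 <= n_selected <= n_features or n_features < 1:
        raise ValueError("need 0 <= n_selected <= n_features, n_features >= 1")
    return 100.0 * (n_features - n_selected) / n_features
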