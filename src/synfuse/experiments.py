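"""Canonical fixture-scale experiment protocol.

The planted-signal study conditions (30 drugs, 10 cell lines, equal unit
signal weights, noise-free scores) with the reduced-width model
configuration used for fast single-CPU experiments.  Both the test suite
and the reproduction script drive these helpers so the protocol is defined
in exactly one place.
"""

from __future__ import annotations

import numpy as np

from .cell_features import AutoencoderSpec
from .model import ModelConfig
from .pipeline import run_experiment
from .simulate import FixtureSpec, generate_fixture


def fixture_spec(seed: int, noise_only: bool = False) -> FixtureSpec:
    """The fixture-scale study conditions.

    ``noise_only`` switches off every signal weight and plants unit
    Gaussian noise instead — the negative control for learnability claims.
    """
    if noise_only:
        return FixtureSpec.small(seed=seed, n_bits=32, w_struct=0.0,
                                 w_target=0.0, w_pathway=0.0, w_cell=0.0,
                                 noise_sd=1.0)
    return FixtureSpec.small(seed=seed, n_bits=32)


def model_config(seed: int, **overrides) -> ModelConfig:
    """Reduced-width model configuration for fixture-scale training."""
    params = dict(h=4, d=32, n_layers=1, cell_dim=16, head_widths=(128, 32),
                  dropout=0.1, batch_size=512, lr=1.5e-3, patience=20,
                  max_epochs=80, seed=seed, augment_swap=True)
    params.update(overrides)
    return ModelConfig(**params)


def autoencoder_spec(seed: int) -> AutoencoderSpec:
    return AutoencoderSpec(hidden=(64, 16), epochs=200, lr=1e-2, seed=seed)


def fixture_scale_run(
    seed: int,
    variant: str = "full",
    folds_to_run: list[int] | None = None,
    noise_only: bool = False,
    **config_overrides,
) -> dict:
    """One cross-validated fixture-scale experiment.

    Pair-disjoint 5-fold CV on the planted-signal (or noise-control)
    fixture; ``folds_to_run`` restricts to a subset of folds, pooling
    out-of-fold predictions over the folds actually run.
    """
    fixture = generate_fixture(fixture_spec(seed, noise_only=noise_only))
    return run_experiment(
        fixture,
        model_cfg=model_config(seed, **config_overrides),
        ae_spec=autoencoder_spec(seed),
        variant=variant,
        k=5,
        split_seed=seed,
        folds_to_run=folds_to_run,
    )


def pooled_pcc(result: dict) -> float:
    return float(result["pooled"]["pcc"])


def pooled_mse(result: dict) -> float:
    return float(result["pooled"]["mse"])


def pca_reconstruction_floor(x: np.ndarray, k: int) -> float:
    """Optimal rank-k reconstruction MSE (PCA on the centred matrix)."""
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    recon = (u[:, :k] * s[:k]) @ vt[:k] + x.mean(axis=0)
    return float(((recon - x) ** 2).mean())
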