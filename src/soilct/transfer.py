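"""Transfer learning: retrain the dense head on a new surrogate target.

The convolutional stack of a trained model is frozen and only the fully
connected layers are trained against a different porosity target. If the
conv layers learned general soil structure, the transferred model should
reach an error of the same order as a from-scratch one while training
far fewer parameters; failures are reported, not hidden.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .surrogate import (RegressionModel, TrainingConfig, TrainingDataset,
                        evaluate_rmse, train)

__all__ = ["freeze_conv", "transfer_train"]


def freeze_conv(model: RegressionModel) -> RegressionModel:
    """Mark every conv-stack layer non-trainable; dense head stays trainable.

    Weights are untouched; the call is idempotent. Raises if the model has
    no dense head to train.
    """
    if not model.dense_head:
        raise ValueError("model has no dense head; nothing would remain trainable")
    for layer in model.conv_stack:
        layer.trainable = False
    return model


def transfer_train(frozen_model: RegressionModel, new_dataset: TrainingDataset,
                   config: TrainingConfig = TrainingConfig(),
                   *, reinit_dense: bool = True,
                   validation: TrainingDataset | None = None,
                   fine_tune: bool = False,
                   fine_tune_lr_factor: float = 0.1
                   ) -> tuple[RegressionModel, pd.DataFrame]:
    """Train only the dense head of a frozen model on a new target.

    The dense head is re-initialized (seeded from ``config.seed``) by
    default so nothing carries over from the previous target. With
    ``fine_tune=True`` a second training phase unfreezes the top conv
    block at a reduced learning rate after the dense-only phase.
    """
    expected = frozen_model.input_extents
    got = new_dataset.images.shape[1:3]
    if tuple(got) != tuple(expected):
        raise ValueError(
            f"dataset images {tuple(got)} incompatible with model input "
            f"{tuple(expected)}")
    freeze_conv(frozen_model)
    if reinit_dense:
        rng = np.random.default_rng(config.seed)
        for layer in frozen_model.dense_head:
            layer.reinitialize(rng)

    before = frozen_model.conv_weights()
    model, history = train(frozen_model, new_dataset, config, validation=validation)
    history = history.assign(phase="dense")

    if fine_tune:
        top_block = _top_conv_block(model)
        for layer in top_block:
            layer.trainable = True
        ft_config = TrainingConfig(
            epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate * fine_tune_lr_factor,
            patience=config.patience, seed=config.seed + 1,
            validation_fraction=config.validation_fraction)
        model, ft_history = train(model, new_dataset, ft_config,
                                  validation=validation)
        history = pd.concat([history, ft_history.assign(phase="fine_tune")],
                            ignore_index=True)
    else:
        after = model.conv_weights()
        for key in before:
            if not np.array_equal(before[key], after[key]):
                raise AssertionError(
                    f"conv weights changed during transfer training: {key}")

    return model, history


def _top_conv_block(model: RegressionModel):
    """Layers of the last conv block (name prefix of the last conv layer)."""
    convs = [l for l in model.conv_stack if l.kind == "conv"]
    if not convs:
        raise ValueError("model has no conv layers")
    prefix = convs[-1].name.split("_")[0]
    return [l for l in model.conv_stack if l.name.startswith(prefix)]


def transfer_report(base_rmse: float, transfer_rmse: float,
                    base_label: str, transfer_label: str) -> pd.DataFrame:
    """Paired (base, transfer) RMSE rows for reporting."""
    return pd.DataFrame([
        {"run": base_label, "kind": "base", "test_rmse": base_rmse},
        {"run": transfer_label, "kind": "dense layer", "test_rmse": transfer_rmse},
    ])
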