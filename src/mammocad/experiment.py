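"""End-to-end phantom experiments at desk scale.

The classification experiment generates a balanced phantom cohort, downsizes
each image to a small network input, trains the depthwise-separable network
under the standard hyperparameters (batch 32, AdaGrad 0.001 with 0.1 decay
every 5 epochs, dropout 0.5, 20 epochs) and evaluates on the held-out
validation split.

Scale choices: phantoms are rendered directly on the 24 x 32 network grid
at 0.7 mm/px (a 17 x 22 mm breast region), so each 0.7 mm MC occupies about
one pixel. Rendering at the working resolution sidesteps resampling: at
this miniature scale any downsizing smears the one-pixel specks into the
parenchymal texture and erases the spatial-arrangement cue the classifier
must learn. Inputs rendered at a different grid are resampled (with
anti-aliasing when downsizing) to the network input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

from .metrics import MetricsReport, full_report
from .netcore import NetworkSpec, build_dcnn, build_fc_dscnn
from .nn import Model
from .phantom import PhantomSpec, generate_dataset
from .trainer import SplitPlan, TrainConfig, make_splits, train_model

__all__ = ["ExperimentResult", "SCALED_PHANTOM_SPEC", "phantom_classification_experiment"]

#: phantom rendering conditions of the scaled-down experiment
SCALED_PHANTOM_SPEC = PhantomSpec(
    width_px=32,
    height_px=24,
    pixel_spacing_mm=0.7,
    n_spots=12,
    diameter_range_mm=(0.7, 0.7),
    spot_contrast=0.5,
    noise_sd=0.01,
    background_level=0.35,
)


@dataclass(frozen=True)
class ExperimentResult:
    report: MetricsReport
    history: List[Dict[str, float]]
    model: Model
    n_train: int
    n_val: int
    input_shape: Tuple[int, int, int]


def _to_network_input(images, input_hw: Tuple[int, int]) -> np.ndarray:
    """Anti-aliased downsize + grayscale-to-RGB replication, stacked NHWC."""
    h, w = input_hw
    out = np.empty((len(images), h, w, 3))
    for i, img in enumerate(images):
        px = img.pixels
        if px.shape != (h, w):
            px = _sk_resize(px, (h, w), order=1,
                            anti_aliasing=px.shape[0] > h or px.shape[1] > w)
        out[i] = px[:, :, None]
    return out


def phantom_classification_experiment(
    n_benign: int = 200,
    n_malignant: int = 200,
    input_hw: Tuple[int, int] = (24, 32),
    seed: int = 42,
    arch: str = "fc-dscnn",
    cfg: Optional[TrainConfig] = None,
    base_spec: PhantomSpec = SCALED_PHANTOM_SPEC,
) -> ExperimentResult:
    """Generate phantoms, train a classifier, and report validation metrics.

    The cohort is split 60/20/20 (stratified); metrics are computed on the
    validation partition at threshold 0.5 with malignant as positive.
    """
    dataset = generate_dataset(n_benign, n_malignant, base_spec, seed=seed)
    images = [img for img, _ in dataset]
    labels = np.array([gt.class_label for _, gt in dataset])

    x = _to_network_input(images, input_hw)
    parts = make_splits(labels, SplitPlan(seed=seed))
    data = {
        "x_train": x[parts["train"]],
        "y_train": labels[parts["train"]],
        "x_val": x[parts["val"]],
        "y_val": labels[parts["val"]],
    }

    input_shape = (input_hw[0], input_hw[1], 3)
    if arch == "fc-dscnn":
        spec = build_fc_dscnn(input_shape)
    elif arch == "dcnn":
        spec = build_dcnn(input_shape)
    else:
        raise ValueError(f"unknown architecture {arch!r}")

    cfg = cfg if cfg is not None else TrainConfig(random_seed=seed)
    model, history = train_model(spec, data, cfg)

    scores = model.predict_proba(data["x_val"])[:, 1]
    report = full_report(data["y_val"], scores, threshold=0.5)
    return ExperimentResult(
        report=report,
        history=history,
        model=model,
        n_train=len(parts["train"]),
        n_val=len(parts["val"]),
        input_shape=input_shape,
    )
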