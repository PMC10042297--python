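"""Exposure-factor robustness experiments.

A trained classifier is applied to cubes multiplied by an exposure factor
``E`` (``E = 1`` is the training condition) and the resulting label maps and
ROI accuracies are recorded.  Three conditions are contrasted:

* ``mono`` — a single-filter (lowest cut-off) image, no normalization
  possible, 1 PC;
* ``multi_unnormalized`` — the 6-channel cube without normalization;
* ``multi_auc`` — the 6-channel cube with AUC = 1 normalization.

For any normalization in {max, auc, snv} the scale factor cancels during
per-spectrum normalization, so label maps are identical across ``E`` — an
identity, not a statistical tendency.  The un-normalized conditions rely on
absolute intensity and degrade when ``E`` moves away from 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cube import ImageCube, apply_exposure_factor
from .classify import ClassifierConfig, TrainedClassifier, fit, predict_cube
from .preprocess import CLASS_LABELS, RoiSet, extract_labeled_spectra

__all__ = [
    "DEFAULT_E_GRID",
    "ExposureSweepResult",
    "accuracy_on_rois",
    "extract_mono",
    "exposure_sweep",
    "mono_vs_multi",
    "plot_sweep",
]

DEFAULT_E_GRID = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 10.0)


@dataclass
class ExposureSweepResult:
    """Per-exposure-factor accuracy and label maps for one condition."""

    condition: str
    E_values: tuple
    accuracies: np.ndarray                 # overall accuracy per E
    per_class_accuracies: np.ndarray       # len(E) x 3
    label_maps: dict                       # E -> H x W label map

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition, "E": list(self.E_values),
            "accuracy": self.accuracies,
            "accuracy_tumor": self.per_class_accuracies[:, 0],
            "accuracy_non_tumor": self.per_class_accuracies[:, 1],
            "accuracy_background": self.per_class_accuracies[:, 2],
        })


def accuracy_on_rois(label_map: np.ndarray, rois: RoiSet) -> tuple[float, np.ndarray]:
    """Overall and per-class fraction correct over labeled ROI pixels only."""
    sel = rois.labeled()
    true = rois.masks[sel]
    pred = label_map[sel]
    overall = float(np.mean(pred == true))
    per_class = np.array([
        np.mean(pred[true == c] == c) if np.any(true == c) else np.nan
        for c in CLASS_LABELS])
    return overall, per_class


def extract_mono(cube: ImageCube, channel: int = 0) -> ImageCube:
    """Single-filter view of a cube (default: the lowest cut-off channel)."""
    return ImageCube(cube.data[..., [channel]],
                     (cube.filter_cutoffs_nm[channel],),
                     exposure_factor=cube.exposure_factor,
                     provenance=dict(cube.provenance))


def exposure_sweep(clf: TrainedClassifier, cube: ImageCube, rois: RoiSet,
                   E_values=DEFAULT_E_GRID, condition: str = "") -> ExposureSweepResult:
    """Apply ``E``-scaled cubes to a classifier trained at ``E = 1``."""
    accs, per_class, maps = [], [], {}
    for E in E_values:
        labels = predict_cube(clf, apply_exposure_factor(cube, E))
        acc, pc = accuracy_on_rois(labels, rois)
        accs.append(acc)
        per_class.append(pc)
        maps[E] = labels
    return ExposureSweepResult(condition or clf.method, tuple(E_values),
                               np.asarray(accs), np.asarray(per_class), maps)


def mono_vs_multi(train_cube: ImageCube, train_rois: RoiSet,
                  test_cube: ImageCube, test_rois: RoiSet,
                  config: ClassifierConfig | None = None,
                  E_values=DEFAULT_E_GRID,
                  method: str = "PCA-KNN",
                  normalization: str = "auc",
                  mono_normalization: str = "none") -> dict:
    """Compare single-filter and multispectral classification under exposure change.

    Trains three classifiers at ``E = 1`` (mono: lowest cut-off channel only,
    1 PC, no normalization; multispectral without normalization; multispectral
    with ``normalization``) and sweeps the test cube over ``E_values``.
    Returns the three :class:`ExposureSweepResult` plus a tidy table.
    """
    if mono_normalization != "none":
        raise ValueError("normalization is not possible with a single wavelength: "
                         "the mono condition has no spectral shape to normalize")
    config = config or ClassifierConfig()

    mono_train = extract_mono(train_cube)
    mono_test = extract_mono(test_cube)
    sweeps = {}
    conditions = [
        ("mono", mono_train, mono_test, "none", replace(config, n_retained=1)),
        ("multi_unnormalized", train_cube, test_cube, "none", config),
        (f"multi_{normalization}", train_cube, test_cube, normalization, config),
    ]
    for name, tr_cube, te_cube, norm, cfg in conditions:
        labeled = extract_labeled_spectra(tr_cube, train_rois, norm)
        clf = fit(method, labeled, cfg)
        sweeps[name] = exposure_sweep(clf, te_cube, test_rois, E_values, condition=name)
    table = pd.concat([s.as_frame() for s in sweeps.values()], ignore_index=True)
    return {"sweeps": sweeps, "table": table}


def plot_sweep(sweeps: dict, path=None):
    """Accuracy-versus-E panel for the three conditions (one axis per condition)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(sweeps), figsize=(4 * len(sweeps), 3.2),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (name, sweep) in zip(axes, sweeps.items()):
        ax.plot(sweep.E_values, 100 * sweep.accuracies, "o-")
        ax.set_xscale("log")
        ax.set_xlabel("exposure factor E")
        ax.set_title(name)
        ax.axvline(1.0, color="0.7", ls="--", lw=0.8)
    axes[0].set_ylabel("ROI accuracy (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
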