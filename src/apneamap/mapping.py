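"""Probabilistic 3D mapping of respiratory outcome from electrode coordinates.

Sparse labelled stimulation sites (midpoint MNI coordinates of stimulated
contact pairs) are turned into voxelwise four-class probability volumes by a
multi-class support vector machine in an error-correcting output-code
arrangement: one RBF-kernel binary SVM per class pair (one-vs-one coding),
decoded by hinge-loss codeword distance and calibrated to probabilities by a
softmax over negative decoded distances. Left-hemisphere sites are reflected
onto the right before fitting, so the learned map lives in one hemisphere.

The peak of the persistent-apnea volume localizes the persistent
amygdala-inhibition-of-respiration (pAIR) site; with a nested generative
model it falls inside the broader apnea (AIR) region.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib
from sklearn.svm import SVC

from .classify import OutcomeLabel, SEVERITY_ORDER, SiteOutcome
from .errors import InvalidParameterError, DegenerateModelWarning

__all__ = [
    "SiteRecord",
    "MappingConfig",
    "OutcomeProbabilityMap",
    "mirror_to_right",
    "fit_outcome_classifier",
    "predict_probability_map",
    "evaluate_loocv",
    "export_map",
    "OutcomeClassifier",
]

CLASS_ORDER = tuple(lbl.value for lbl in SEVERITY_ORDER)


@dataclass(frozen=True)
class SiteRecord:
    """One stimulated contact pair in common (MNI-style, RAS mm) space."""

    patient_id: str
    site_id: str
    coordinate: tuple
    hemisphere: str
    region_label: str
    outcome: SiteOutcome
    true_label: OutcomeLabel | None = None

    def __post_init__(self):
        coord = tuple(float(v) for v in self.coordinate)
        if len(coord) != 3 or not all(np.isfinite(coord)):
            raise InvalidParameterError("coordinate must be a finite 3-vector (mm)")
        object.__setattr__(self, "coordinate", coord)
        if self.hemisphere not in ("left", "right"):
            raise InvalidParameterError("hemisphere must be 'left' or 'right'")


@dataclass
class MappingConfig:
    """Classifier and grid hyperparameters (unstated in the source study;
    defaults are robust for ~90 points in 3D and fully configurable)."""

    kernel: str = "rbf"
    margin_penalty: float = 1.0
    kernel_scale: float | None = None  # None -> kernel_scale_frac * median pairwise distance
    kernel_scale_frac: float = 0.5
    coding: str = "one_vs_one"
    calibration: str = "distance_softmax"  # or "pairwise_coupling"
    grid_spacing_mm: float = 1.0
    pad_mm: float = 10.0
    standardize: bool = True
    balance_classes: bool = True  # rare classes (persistent apnea) still shape the map

    def __post_init__(self):
        if not self.grid_spacing_mm > 0:
            raise InvalidParameterError("grid spacing must be positive")
        if not self.margin_penalty > 0:
            raise InvalidParameterError("margin penalty C must be positive")
        if self.coding != "one_vs_one":
            raise InvalidParameterError("only one_vs_one coding is implemented")
        if self.calibration not in ("distance_softmax", "pairwise_coupling"):
            raise InvalidParameterError("unknown calibration method")


@dataclass(frozen=True)
class OutcomeProbabilityMap:
    """Voxel grid of per-class posterior probabilities (RAS mm)."""

    origin: tuple
    spacing: float
    shape: tuple
    volumes: np.ndarray  # (n_classes, nx, ny, nz)
    class_order: tuple = CLASS_ORDER

    def volume(self, label) -> np.ndarray:
        return self.volumes[self.class_order.index(OutcomeLabel(label).value)]

    def peak_coordinate(self, label) -> np.ndarray:
        vol = self.volume(label)
        idx = np.unravel_index(int(np.argmax(vol)), vol.shape)
        return np.asarray(self.origin) + self.spacing * np.asarray(idx)

    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff


def mirror_to_right(sites: list[SiteRecord]) -> list[SiteRecord]:
    """Project left-hemisphere sites onto the right by |x| reflection.

    Only the left-right coordinate changes sign; all other fields are kept.
    Idempotent by construction.
    """
    out = []
    for s in sites:
        x, y, z = s.coordinate
        out.append(
            replace(s, coordinate=(abs(x), y, z), hemisphere="right")
            if x < 0
            else replace(s, coordinate=(abs(x), y, z))
        )
    return out


class OutcomeClassifier:
    """One-vs-one ECOC of RBF SVMs over mirrored, standardized coordinates."""

    def __init__(self, config: MappingConfig):
        self.config = config
        self.classes_: list[str] = []
        self._pairs: list[tuple[int, int]] = []
        self._svms: list[SVC] = []
        self._mean = np.zeros(3)
        self._std = np.ones(3)
        self._bbox: tuple | None = None
        self._degenerate: str | None = None

    # -- fitting ---------------------------------------------------------

    def fit(self, coords: np.ndarray, labels: list[str]) -> "OutcomeClassifier":
        coords = np.asarray(coords, dtype=float)
        labels = [OutcomeLabel(l).value for l in labels]
        self._bbox = (coords.min(axis=0), coords.max(axis=0))
        present = [c for c in CLASS_ORDER if c in labels]
        self.classes_ = present
        if len(present) < 2:
            self._degenerate = present[0]
            warnings.warn(
                f"single-class training data; constant map predicting {present[0]!r}",
                DegenerateModelWarning,
                stacklevel=2,
            )
            return self
        if self.config.standardize:
            self._mean = coords.mean(axis=0)
            self._std = np.where(coords.std(axis=0) > 0, coords.std(axis=0), 1.0)
        X = (coords - self._mean) / self._std
        if self.config.kernel_scale is not None:
            scale = self.config.kernel_scale
        else:
            # half the median pairwise distance: the full median over-smooths
            # focal clusters much smaller than the site cloud
            d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
            scale = self.config.kernel_scale_frac * float(
                np.median(d[np.triu_indices_from(d, k=1)])
            )
            scale = scale if scale > 0 else 1.0
        gamma = 1.0 / (2.0 * scale**2)
        y = np.array([present.index(l) for l in labels])
        probability = self.config.calibration == "pairwise_coupling"
        self._pairs, self._svms = [], []
        for i, j in itertools.combinations(range(len(present)), 2):
            mask = (y == i) | (y == j)
            yy = np.where(y[mask] == i, 1, -1)
            kwargs = dict(
                C=self.config.margin_penalty,
                kernel=self.config.kernel,
                gamma=gamma,
                class_weight="balanced" if self.config.balance_classes else None,
                random_state=0,
            )
            if probability:
                kwargs["probability"] = True
            svm = SVC(**kwargs)
            svm.fit(X[mask], yy)
            self._pairs.append((i, j))
            self._svms.append(svm)
        return self

    # -- prediction ------------------------------------------------------

    def _transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float)).copy()
        coords[:, 0] = np.abs(coords[:, 0])  # same reflection as training
        return (coords - self._mean) / self._std

    def predict_proba(self, coords: np.ndarray) -> np.ndarray:
        """Four-class probabilities (columns in severity order) per coordinate."""
        coords2 = np.atleast_2d(np.asarray(coords, dtype=float))
        n = coords2.shape[0]
        out = np.zeros((n, len(CLASS_ORDER)))
        if self._degenerate is not None:
            out[:, CLASS_ORDER.index(self._degenerate)] = 1.0
            return out
        X = self._transform(coords2)
        k = len(self.classes_)
        if self.config.calibration == "pairwise_coupling":
            p = np.zeros((n, k))
            for (i, j), svm in zip(self._pairs, self._svms):
                pij = svm.predict_proba(X)  # columns for classes [-1, +1]
                p[:, i] += pij[:, list(svm.classes_).index(1)]
                p[:, j] += pij[:, list(svm.classes_).index(-1)]
            p /= p.sum(axis=1, keepdims=True)
        else:
            # codeword-distance decoding with a smoothed hinge (softplus)
            # loss; strictly monotone in the margin, so decoded distances
            # carry depth-in-region information instead of zero-clipping
            dist = np.zeros((n, k))
            for (i, j), svm in zip(self._pairs, self._svms):
                f = svm.decision_function(X)
                dist[:, i] += np.logaddexp(0.0, 1.0 - f)
                dist[:, j] += np.logaddexp(0.0, 1.0 + f)
            z = -dist
            z -= z.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
        for idx, cls in enumerate(self.classes_):
            out[:, CLASS_ORDER.index(cls)] = p[:, idx]
        return out

    def predict(self, coords: np.ndarray) -> list[str]:
        proba = self.predict_proba(coords)
        return [CLASS_ORDER[int(i)] for i in np.argmax(proba, axis=1)]


def fit_outcome_classifier(
    sites: list[SiteRecord], config: MappingConfig | None = None
) -> OutcomeClassifier:
    """Fit the multi-class outcome classifier to labelled sites.

    Left-sided coordinates are reflected to the right hemisphere first, so
    mirroring the inputs beforehand changes nothing. Raises on fewer than 5
    sites; single-class input degenerates to a constant map with a warning.
    """
    config = config or MappingConfig()
    if len(sites) < 5:
        raise InvalidParameterError("need at least 5 sites to fit")
    mirrored = mirror_to_right(sites)
    coords = np.array([s.coordinate for s in mirrored])
    labels = [OutcomeLabel(s.outcome.label).value for s in mirrored]
    missing = [c for c in CLASS_ORDER if c not in labels]
    if missing and len(set(labels)) >= 2:
        warnings.warn(
            f"classes absent from training get zero probability: {missing}",
            DegenerateModelWarning,
            stacklevel=2,
        )
    return OutcomeClassifier(config).fit(coords, labels)


def predict_probability_map(
    model: OutcomeClassifier, config: MappingConfig | None = None
) -> OutcomeProbabilityMap:
    """Evaluate class probabilities on an isotropic grid over the padded
    bounding box of the training sites."""
    config = config or model.config
    if model._bbox is None:
        raise InvalidParameterError("model is not fitted")
    lo = np.asarray(model._bbox[0]) - config.pad_mm
    hi = np.asarray(model._bbox[1]) + config.pad_mm
    lo[0] = max(lo[0], 0.0)  # the fitted map lives in the right hemisphere
    axes = [np.arange(l, h + config.grid_spacing_mm / 2, config.grid_spacing_mm) for l, h in zip(lo, hi)]
    shape = tuple(len(a) for a in axes)
    if any(s == 0 for s in shape):
        raise InvalidParameterError("empty prediction grid")
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    proba = np.empty((pts.shape[0], len(CLASS_ORDER)))
    step = 20000
    for i in range(0, pts.shape[0], step):
        proba[i : i + step] = model.predict_proba(pts[i : i + step])
    volumes = proba.T.reshape((len(CLASS_ORDER),) + shape)
    return OutcomeProbabilityMap(
        origin=tuple(float(a[0]) for a in axes),
        spacing=config.grid_spacing_mm,
        shape=shape,
        volumes=volumes,
    )


def evaluate_loocv(sites: list[SiteRecord], config: MappingConfig | None = None):
    """Leave-one-site-out predicted labels, confusion matrix and accuracy."""
    import pandas as pd

    config = config or MappingConfig()
    n = len(sites)
    preds, truth = [], []
    for i in range(n):
        train = sites[:i] + sites[i + 1 :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateModelWarning)
            model = fit_outcome_classifier(train, config)
        preds.append(model.predict([sites[i].coordinate])[0])
        truth.append(OutcomeLabel(sites[i].outcome.label).value)
    conf = pd.DataFrame(0, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))
    for t, p in zip(truth, preds):
        conf.loc[t, p] += 1
    acc = float(np.mean([t == p for t, p in zip(truth, preds)]))
    return {"accuracy": acc, "confusion": conf, "predicted": preds, "true": truth}


def export_map(pmap: OutcomeProbabilityMap, path_stem) -> list[str]:
    """Write one float32 NIfTI-1 volume per class: ``<stem>_<class>.nii.gz``.

    The affine maps voxel (0, 0, 0) to the grid origin with isotropic
    ``spacing`` mm voxels.
    """
    paths = []
    for cls in pmap.class_order:
        img = nib.Nifti1Image(pmap.volume(cls).astype(np.float32), pmap.affine())
        p = f"{path_stem}_{cls}.nii.gz"
        nib.save(img, p)
        paths.append(p)
    return paths
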