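"""Initial location of the lesion's key boundary points.

Two interchangeable initializers play the role of the first stage of the
cascade: a deterministic dark-blob heuristic, and a small trainable
multitask network with a lesion-presence head and a coordinate-regression
head.  Either produces an :class:`InitialPoints` pair that seeds the
reinforcement-learning refiner and fixes its active region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border
from skimage.transform import resize
from sklearn.base import BaseEstimator

from . import _nn
from .phantom import Annotation, BScan

__all__ = ["InitialPoints", "heuristic_initializer", "MultitaskInitializer",
           "train_multitask_initializer", "predict_initial"]


@dataclass(frozen=True)
class InitialPoints:
    """Initial (x, y) estimates for the left and right boundary points."""

    left: tuple[int, int]
    right: tuple[int, int]
    source: str = "heuristic"   # {"heuristic", "cnn"}
    warning: bool = False       # True when a fallback was used


def _clamp_point(x: float, y: float, scan: BScan) -> tuple[int, int]:
    return (int(np.clip(round(x), 0, scan.width - 1)),
            int(np.clip(round(y), 0, scan.height - 1)))


def heuristic_initializer(scan: BScan) -> InitialPoints:
    """Locate the lesion as the largest enclosed dark blob.

    Thresholds at the between-class-variance (Otsu) level, discards dark
    regions touching the border (vitreous background), and keeps the
    largest remaining component whose centroid falls in the central half of
    the image.  Its extreme columns give the two boundary points.  If no
    such component exists the image-center fallback is returned with a
    warning flag.
    """
    img = scan.pixels
    h, w = img.shape
    fallback = InitialPoints(left=(w // 2 - w // 4, h // 2),
                             right=(w // 2 + w // 4, h // 2),
                             source="heuristic", warning=True)
    flat = img.ravel()
    if flat.max() == flat.min():
        return fallback
    thresh = threshold_otsu(img)
    dark = img < thresh
    dark = clear_border(dark)
    if not dark.any():
        return fallback
    labels = label(dark)
    best = None
    for region in regionprops(labels):
        cy, cx = region.centroid
        if not (w / 4 <= cx <= 3 * w / 4 and h / 4 <= cy <= 3 * h / 4):
            continue
        if best is None or region.area > best.area:
            best = region
    if best is None:
        return fallback
    coords = best.coords  # (row, col) pairs
    cols = coords[:, 1]
    left_col, right_col = cols.min(), cols.max()
    # the dome is widest at its base, so take the bottom pixel per extreme
    left_row = coords[cols == left_col][:, 0].max()
    right_row = coords[cols == right_col][:, 0].max()
    return InitialPoints(left=(int(left_col), int(left_row)),
                         right=(int(right_col), int(right_row)),
                         source="heuristic", warning=False)


class MultitaskInitializer(BaseEstimator):
    """Two-headed dense network: lesion presence + boundary coordinates.

    Images are resized to ``input_size`` squared, scaled to [0, 1] and
    flattened; a shared trunk feeds a presence logit (binary cross-entropy)
    and four normalized coordinates ``(x_L, y_L, x_R, y_R)`` (smooth-L1),
    summed with configurable weights.  Coordinates are normalized by the
    original image size so a model transfers across resolutions.

    Parameters
    ----------
    epochs, learning_rate, batch_size : training schedule; defaults 40,
        0.001, 20 with adaptive-moment updates.
    presence_weight, coord_weight : weights of the two loss terms.
    hidden : width of the trunk's hidden layers.
    input_size : side of the resized square input.
    seed : initialization and shuffling seed.
    """

    def __init__(self, epochs: int = 40, learning_rate: float = 0.001,
                 batch_size: int = 20, presence_weight: float = 1.0,
                 coord_weight: float = 1.0, hidden: tuple = (96,),
                 input_size: int = 32, seed: int = 0):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.presence_weight = presence_weight
        self.coord_weight = coord_weight
        self.hidden = hidden
        self.input_size = input_size
        self.seed = seed

    # -- internals ---------------------------------------------------------
    def _features(self, scans) -> np.ndarray:
        s = self.input_size
        out = np.empty((len(scans), s * s), dtype=np.float32)
        for i, scan in enumerate(scans):
            small = resize(scan.pixels.astype(np.float64) / 255.0, (s, s),
                           anti_aliasing=True)
            out[i] = small.ravel().astype(np.float32)
        return out

    def _targets(self, scans, annotations) -> np.ndarray:
        t = np.empty((len(scans), 4), dtype=np.float32)
        for i, (scan, ann) in enumerate(zip(scans, annotations)):
            lx, ly = ann.left_point
            rx, ry = ann.right_point
            t[i] = [lx / (scan.width - 1), ly / (scan.height - 1),
                    rx / (scan.width - 1), ry / (scan.height - 1)]
        return t

    def _build(self, rng) -> None:
        dims = [self.input_size ** 2, *self.hidden]
        layers = []
        for a, b in zip(dims, dims[1:]):
            layers += [_nn.Dense(a, b, rng), _nn.ReLU()]
        self._trunk = _nn.Sequential(layers)
        self._head_presence = _nn.Dense(dims[-1], 1, rng)
        self._head_coords = _nn.Dense(dims[-1], 4, rng)

    # -- estimator API -----------------------------------------------------
    def fit(self, scans, annotations, presence=None):
        """Train on aligned lists of scans and annotations.

        ``presence`` optionally marks lesion-free images (0); by default
        every training image contains a lesion (1).
        """
        if len(scans) == 0:
            raise ValueError("training set must contain at least one image")
        if len(scans) != len(annotations):
            raise ValueError("scans and annotations must be aligned")
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        X = self._features(scans)
        Y = self._targets(scans, annotations)
        pres = (np.ones((len(scans), 1), dtype=np.float32) if presence is None
                else np.asarray(presence, dtype=np.float32).reshape(-1, 1))
        params = (self._trunk.params + self._head_presence.params
                  + self._head_coords.params)
        opt = _nn.Adam(params, lr=self.learning_rate)
        n = len(scans)
        bs = min(self.batch_size, n)
        curve = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                h = self._trunk.forward(X[idx])
                logit = self._head_presence.forward(h)
                coords = self._head_coords.forward(h)
                loss = (self.presence_weight * _nn.bce_with_logits(logit, pres[idx])
                        + self.coord_weight * _nn.smooth_l1(coords, Y[idx]))
                d_logit = self.presence_weight * _nn.bce_with_logits_grad(
                    logit, pres[idx])
                d_coords = self.coord_weight * _nn.smooth_l1_grad(coords, Y[idx])
                dh = (self._head_presence.backward(d_logit)
                      + self._head_coords.backward(d_coords))
                self._trunk.backward(dh)
                grads = (self._trunk.grads + self._head_presence.grads
                         + self._head_coords.grads)
                opt.step(grads)
                losses.append(loss)
            curve.append(float(np.mean(losses)))
        self.loss_curve_ = curve
        self.final_loss_ = curve[-1]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, scans) -> list[InitialPoints]:
        """Initial points for each scan, rounded and clamped inside bounds."""
        if not hasattr(self, "loss_curve_"):
            raise RuntimeError("MultitaskInitializer is not fitted")
        X = self._features(scans)
        h = self._trunk.forward(X)
        coords = self._head_coords.forward(h)
        out = []
        for scan, c in zip(scans, coords):
            left = _clamp_point(c[0] * (scan.width - 1),
                                c[1] * (scan.height - 1), scan)
            right = _clamp_point(c[2] * (scan.width - 1),
                                 c[3] * (scan.height - 1), scan)
            out.append(InitialPoints(left=left, right=right, source="cnn"))
        return out

    def predict_presence(self, scans) -> np.ndarray:
        """Lesion-presence probability per scan."""
        X = self._features(scans)
        h = self._trunk.forward(X)
        logit = self._head_presence.forward(h)
        return 1.0 / (1.0 + np.exp(-logit.ravel().astype(np.float64)))


def train_multitask_initializer(scans, annotations,
                                config: dict | None = None,
                                seed: int = 0) -> MultitaskInitializer:
    """Functional wrapper over :class:`MultitaskInitializer`."""
    model = MultitaskInitializer(seed=seed, **(config or {}))
    return model.fit(scans, annotations)


def predict_initial(model, scan: BScan) -> InitialPoints:
    """Predict with either a fitted model or the heuristic (``model=None``)."""
    if model is None:
        return heuristic_initializer(scan)
    return model.predict([scan])[0]
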