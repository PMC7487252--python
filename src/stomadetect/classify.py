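"""Patch classifier: a scikit-learn estimator over the NumPy CNN backend.

:class:`PatchCNNClassifier` follows the scikit-learn contract
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params``), so it plugs
into pipelines and model selection.  Inputs are square intensity patches
(grayscale ``(n, P, P)`` or RGB ``(n, P, P, 3)``) in [0, 1], internally
centered to [−0.5, 0.5]; the output is a two-way softmax giving absence
and presence probabilities that sum to 1.

The module-level :func:`build_classifier`, :func:`train` and
:func:`score_patch` are thin functional wrappers over the estimator.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .architectures import (ArchitectureSpec, TrainingHyperparams,
                            count_parameters, get_architecture)
from .nn import Adam, SequentialNet, softmax_cross_entropy
from .patches import Patch, PatchDataset

__all__ = ["PatchCNNClassifier", "build_classifier", "train", "score_patch"]


def _as_batch(X: np.ndarray, size: int) -> np.ndarray:
    """Coerce patches to (n, size, size, 3) float32, centered.

    Intensities are scaled to [0, 1] then shifted by −0.5: removing the
    large common (background) component keeps the early feature maps from
    being dominated by it, which conditions training far better than raw
    [0, 1] input on these pale micrographs.
    """
    X = np.asarray(X)
    if X.ndim == 2:
        X = X[None]
    if X.ndim == 3:
        X = X[..., None].repeat(3, axis=3)
    if X.ndim != 4 or X.shape[3] != 3:
        raise ValueError("patches must be (n, P, P) grayscale or (n, P, P, 3) RGB")
    if X.shape[1] != size or X.shape[2] != size:
        raise ValueError(
            f"patch size {X.shape[1]}x{X.shape[2]} does not match the "
            f"classifier input {size}x{size}"
        )
    if np.issubdtype(X.dtype, np.integer):
        X = X.astype(np.float32) / 255.0
    return np.ascontiguousarray(X, dtype=np.float32) - np.float32(0.5)


def _augment_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-sample random square symmetry (90° rotations + flips), in place."""
    ks = rng.integers(4, size=len(xb))
    fh = rng.integers(2, size=len(xb))
    fv = rng.integers(2, size=len(xb))
    out = np.empty_like(xb)
    for i in range(len(xb)):
        t = np.rot90(xb[i], int(ks[i]), axes=(0, 1))
        if fh[i]:
            t = t[:, ::-1]
        if fv[i]:
            t = t[::-1]
        out[i] = t
    return out


class PatchCNNClassifier(BaseEstimator, ClassifierMixin):
    """CNN classifier for stoma presence in fixed-size patches.

    Parameters
    ----------
    architecture : {"basic_shallow", "basic_deep", "vgg19"}
        Which declared architecture to instantiate.
    learning_rate, batch_size, epochs : optional
        Override the per-architecture Adam defaults (5e-4/32/200 for
        basic_shallow, 5e-5/64/200 for basic_deep, 5e-6/128/50 for vgg19).
    dropout_rate : float, default 0.5
        Inverted dropout on the dense layers during training.
    augment : bool, default True
        On-the-fly random 90°-rotations and flips of each training batch.
    random_state : int, default 0
        Seeds initialization, batch order, dropout and augmentation.

    Attributes
    ----------
    net_ : SequentialNet
        The instantiated network (after ``fit`` or ``initialize``).
    history_ : dict
        Per-epoch training ``loss`` and ``accuracy``.
    classes_ : ndarray
        ``[0, 1]`` — absence / presence.
    """

    def __init__(self, architecture: str = "basic_shallow",
                 learning_rate: float | None = None,
                 batch_size: int | None = None,
                 epochs: int | None = None,
                 dropout_rate: float = 0.5,
                 augment: bool = True,
                 random_state: int = 0,
                 verbose: int = 0):
        self.architecture = architecture
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout_rate = dropout_rate
        self.augment = augment
        self.random_state = random_state
        self.verbose = verbose

    # -- construction ----------------------------------------------------
    def _hyper(self) -> TrainingHyperparams:
        overrides = {k: v for k, v in dict(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
        ).items() if v is not None}
        return TrainingHyperparams.for_architecture(
            self.architecture, dropout_rate=self.dropout_rate,
            augmentation=self.augment, seed=self.random_state, **overrides)

    def initialize(self) -> "PatchCNNClassifier":
        """Build the network with fresh (seeded) weights, without training."""
        spec = get_architecture(self.architecture)
        if spec.frozen_prefix and self.architecture == "vgg19":
            warnings.warn(
                "no pretrained convolutional weights available; the frozen "
                "vgg19 base uses random initialization", stacklevel=2)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 0xC0FFEE]))
        self.spec_ = spec
        self.net_ = SequentialNet(spec, rng, dropout_rate=self.dropout_rate)
        self.classes_ = np.array([0, 1])
        self.input_size_ = spec.input_shape[0]
        self.history_ = {"loss": [], "accuracy": []}
        return self

    @property
    def num_params(self) -> int:
        """Total parameter count of the instantiated network."""
        check_is_fitted(self, "net_")
        return self.net_.num_params()

    @property
    def num_frozen_params(self) -> int:
        check_is_fitted(self, "spec_")
        total, trainable = count_parameters(self.spec_)
        return total - trainable

    # -- training --------------------------------------------------------
    def fit(self, X, y) -> "PatchCNNClassifier":
        if isinstance(X, PatchDataset):
            X, y = X.X, X.y
        y = np.asarray(y).astype(np.int64).ravel()
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1 (absence/presence)")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self.initialize()
        X = _as_batch(X, self.input_size_)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        hyper = self._hyper()
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 0x712A1]))
        opt = Adam(self.net_, hyper.learning_rate, hyper.beta1, hyper.beta2)
        n = len(X)
        bs = min(hyper.batch_size, n)
        for epoch in range(hyper.epochs):
            perm = rng.permutation(n)
            tot_loss = 0.0
            tot_correct = 0
            for start in range(0, n, bs):
                idx = perm[start:start + bs]
                xb = X[idx]
                if hyper.augmentation:
                    xb = _augment_batch(xb, rng)
                yb = y[idx]
                probs = self.net_.forward(xb, train=True, rng=rng)
                loss = softmax_cross_entropy(probs, yb)
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                self.net_.backward(dlogits.astype(np.float32))
                opt.step()
                tot_loss += loss * len(yb)
                tot_correct += int((probs.argmax(axis=1) == yb).sum())
            self.history_["loss"].append(tot_loss / n)
            self.history_["accuracy"].append(tot_correct / n)
            if self.verbose:
                print(f"epoch {epoch + 1}/{hyper.epochs}: "
                      f"loss {tot_loss / n:.4f} acc {tot_correct / n:.3f}")
        return self

    # -- inference -------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = _as_batch(X, self.input_size_)
        out = np.empty((len(X), 2), dtype=np.float32)
        for start in range(0, len(X), 256):
            out[start:start + 256] = self.net_.forward(X[start:start + 256])
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score_patch(self, patch) -> float:
        """Presence-class probability for one patch (Patch or array)."""
        px = patch.pixels if isinstance(patch, Patch) else patch
        return float(self.predict_proba(px[None] if px.ndim == 2 else
                                        np.asarray(px)[None])[0, 1])


# -- functional wrappers -------------------------------------------------

def build_classifier(spec: ArchitectureSpec | str,
                     hyper: TrainingHyperparams | None = None
                     ) -> PatchCNNClassifier:
    """Instantiate an untrained classifier honoring the scoring contract."""
    name = spec if isinstance(spec, str) else spec.name
    kw = {}
    if hyper is not None:
        kw = dict(learning_rate=hyper.learning_rate, batch_size=hyper.batch_size,
                  epochs=hyper.epochs, dropout_rate=hyper.dropout_rate,
                  augment=hyper.augmentation, random_state=hyper.seed)
    return PatchCNNClassifier(architecture=name, **kw).initialize()


def train(clf: PatchCNNClassifier, ds: PatchDataset,
          hyper: TrainingHyperparams | None = None) -> PatchCNNClassifier:
    """Fit ``clf`` on a patch dataset; returns the fitted estimator."""
    if hyper is not None:
        clf.set_params(learning_rate=hyper.learning_rate,
                       batch_size=hyper.batch_size, epochs=hyper.epochs,
                       dropout_rate=hyper.dropout_rate,
                       augment=hyper.augmentation, random_state=hyper.seed)
    return clf.fit(ds.X, ds.y)


def score_patch(clf: PatchCNNClassifier, patch) -> float:
    return clf.score_patch(patch)
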