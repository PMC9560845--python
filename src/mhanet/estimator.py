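"""scikit-learn style estimator facade.

:class:`MHANetSegmenter` wraps model construction, the training loop, and
padded prediction behind the familiar ``fit``/``predict`` contract so the
network composes with sklearn pipelines and model selection. Inputs are
plain arrays: ``X`` is (n, H, W, 3) float in [0, 1], ``y`` is (n, H, W)
binary. ``score`` returns the mean Dice coefficient, so higher is better
under sklearn conventions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import crop_back, pad_to_stride, to_batch
from .decoder import ModelConfig, assemble_mhanet
from .metrics import confusion_counts, dice
from .train import TrainConfig, train


class MHANetSegmenter(BaseEstimator):
    """Encoder/decoder segmentation network with pyramid split attention.

    Parameters
    ----------
    width_scale : float
        Global channel multiplier; 1.0 is the full 36.9 M-parameter
        network, 0.25 a desk-scale variant.
    use_psa, use_se, use_sum : bool
        Ablation switches for the attention bridge, the decoder channel
        attention, and the additive skip branch.
    epochs, batch_size, learning_rate : training protocol (Adam, BCE).
    threshold : float
        Probability threshold used by :meth:`predict` and :meth:`score`.
    val_fraction : float
        Fraction of ``fit`` data held out for best-checkpoint selection;
        0 keeps the final state.
    seed : int
        Controls initialization and shuffling; same seed, same model.
    """

    def __init__(
        self,
        width_scale: float = 0.25,
        use_psa: bool = True,
        use_se: bool = True,
        use_sum: bool = True,
        epochs: int = 30,
        batch_size: int = 4,
        learning_rate: float = 1e-4,
        threshold: float = 0.5,
        val_fraction: float = 0.0,
        seed: int = 0,
    ):
        self.width_scale = width_scale
        self.use_psa = use_psa
        self.use_se = use_se
        self.use_sum = use_sum
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.val_fraction = val_fraction
        self.seed = seed

    # -- sklearn plumbing --------------------------------------------------
    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (n, H, W, 3), got {X.shape}")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("X values must lie in [0, 1]")
        if y is None:
            return X
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise ValueError(f"y must be (n, H, W) matching X, got {y.shape}")
        return X, y

    def fit(self, X, y):
        X, y = self._validate_xy(X, y)
        config = ModelConfig(
            width_scale=self.width_scale,
            use_psa=self.use_psa,
            use_se=self.use_se,
            use_sum=self.use_sum,
            seed=self.seed,
        )
        self.model_ = assemble_mhanet(config)
        self.config_ = self.model_.config
        records = [(X[i], y[i].astype(np.uint8)) for i in range(len(X))]
        n_val = int(round(self.val_fraction * len(records)))
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(records))
        val = [records[i] for i in order[:n_val]]
        tr = [records[i] for i in order[n_val:]]
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
            threshold=self.threshold,
        )
        best_state, self.history_ = train(self.model_, tr, val, cfg)
        self.model_.load_state_dict(best_state)
        self.n_parameters_ = self.model_.num_params()
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("this MHANetSegmenter instance is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        """(n, H, W) sigmoid probability maps."""
        self._check_fitted()
        X = self._validate_xy(X)
        out = []
        for i in range(len(X)):
            img_p, crop = pad_to_stride(X[i])
            prob = self.model_.predict_proba(to_batch([img_p]))[0, 0]
            out.append(crop_back(prob, crop))
        return np.stack(out)

    def predict(self, X) -> np.ndarray:
        """(n, H, W) binary masks thresholded at ``self.threshold``."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice coefficient over the batch (1.0 is a perfect overlap)."""
        X, y = self._validate_xy(X, y)
        preds = self.predict(X)
        return float(
            np.mean(
                [dice(confusion_counts(p, t.astype(np.uint8))) for p, t in zip(preds, y)]
            )
        )
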