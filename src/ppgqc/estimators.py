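"""Scikit-learn estimator interface to the three PPG quality classifiers.

Each estimator wraps one architecture family behind the familiar
``fit`` / ``predict`` / ``predict_proba`` contract, so the classifiers
compose with sklearn pipelines, cross-validation and grid-search
machinery.  ``fit`` accepts an optional ``validation_data=(X_val, y_val)``
pair; without one, a stratified ``validation_fraction`` of the training
data is held out internally for early stopping and checkpoint selection.

Example
-------
>>> from ppgqc.estimators import CNNKANClassifier
>>> clf = CNNKANClassifier(max_epochs=20, random_state=0)
>>> clf.fit(X_train, y_train).score(X_test, y_test)  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .architectures import ModelConfig, count_trainable_parameters
from .kan import SplineSpec
from .train import TrainConfig, stratified_split_indices, train
from .architectures import build_model

__all__ = ["CNNLSTMClassifier", "CNNMLPClassifier", "CNNKANClassifier"]


class _BaseCNNClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing; subclasses define the architecture."""

    _family: str = ""

    # ---- architecture config, provided by subclasses -------------------
    def _model_config(self, input_length: int) -> ModelConfig:
        raise NotImplementedError

    # ---- sklearn API ----------------------------------------------------
    def fit(self, X, y, validation_data=None):
        """Train on (X, y); X has one preprocessed segment per row.

        Parameters
        ----------
        validation_data : tuple (X_val, y_val), optional
            Held-out set driving early stopping and best-epoch selection.
            When omitted, a stratified ``validation_fraction`` of (X, y)
            is split off internally.
        """
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"binary classifier needs exactly 2 classes, got {self.classes_.size}"
            )
        y_bin = (y == self.classes_[1]).astype(np.int64)
        self.n_features_in_ = X.shape[1]

        if validation_data is not None:
            x_val, y_val = validation_data
            x_val = check_array(x_val, dtype=np.float64)
            y_val = (np.asarray(y_val) == self.classes_[1]).astype(np.int64)
            x_tr, y_tr = X, y_bin
        else:
            frac = self.validation_fraction
            if not 0.0 < frac < 1.0:
                raise ValueError(f"validation_fraction must be in (0, 1), got {frac}")
            # reuse the 3-way splitter; fold its test part into validation
            tr, va, te = stratified_split_indices(
                y_bin, (1.0 - frac, frac / 2, frac / 2), seed=self._seed()
            )
            va = np.concatenate([va, te])
            x_tr, y_tr = X[tr], y_bin[tr]
            x_val, y_val = X[va], y_bin[va]

        cfg = self._model_config(self.n_features_in_)
        rng = np.random.default_rng(self._seed())
        network = build_model(cfg, rng)
        train_cfg = TrainConfig(
            max_epochs=self.max_epochs,
            patience=min(self.patience, self.max_epochs),
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self._seed(),
            threshold=self.threshold,
        )
        network, history = train(network, (x_tr, y_tr), (x_val, y_val), train_cfg)
        self.network_ = network
        self.config_ = cfg
        self.history_ = history
        self.n_parameters_ = count_trainable_parameters(network)
        self.best_epoch_ = history["best_epoch"]
        self.val_loss_ = history["best_val_loss"]
        return self

    def decision_function(self, X):
        """Raw pre-sigmoid scores (logits) for the positive class."""
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; expected {self.n_features_in_}"
            )
        return self.network_.forward(X, train=False)[:, 0]

    def predict_proba(self, X):
        from .nn import sigmoid

        p1 = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 >= self.threshold).astype(int)]

    def _seed(self) -> int:
        return 0 if self.random_state is None else int(self.random_state)


class CNNLSTMClassifier(_BaseCNNClassifier):
    """Conv + batch-norm + stacked bidirectional LSTM PPG quality classifier.

    The convolution (kernel 15, stride 4) extracts local waveform shapes
    and shortens the sequence; two bidirectional LSTM layers of hidden size
    56 track pulse timing; global average pooling and a [112, 64] dense
    stack produce the good-vs-fair/poor probability.
    """

    _family = "cnn_lstm"

    def __init__(self, conv_kernel=15, conv_channels=8, conv_stride=4,
                 lstm_hidden=56, lstm_layers=2, bidirectional=True,
                 ff_dims=(112, 64), max_epochs=200, patience=50,
                 learning_rate=1e-3, batch_size=32, threshold=0.5,
                 validation_fraction=0.25, random_state=0):
        self.conv_kernel = conv_kernel
        self.conv_channels = conv_channels
        self.conv_stride = conv_stride
        self.lstm_hidden = lstm_hidden
        self.lstm_layers = lstm_layers
        self.bidirectional = bidirectional
        self.ff_dims = ff_dims
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _model_config(self, input_length: int) -> ModelConfig:
        return ModelConfig.cnn_lstm(
            input_length=input_length,
            conv_kernel=self.conv_kernel,
            conv_channels=self.conv_channels,
            conv_stride=self.conv_stride,
            lstm_hidden=self.lstm_hidden,
            lstm_layers=self.lstm_layers,
            lstm_bidirectional=self.bidirectional,
            ff_dims=tuple(self.ff_dims),
        )


class CNNMLPClassifier(_BaseCNNClassifier):
    """Conv + max-pool + channel-average + dense-stack PPG quality classifier.

    The default head [100, 50, 25, 10] gradually reduces the pooled
    sequence to a single sigmoid output.
    """

    _family = "cnn_mlp"

    def __init__(self, conv_kernel=5, conv_channels=5, pool_size=4,
                 ff_dims=(100, 50, 25, 10), max_epochs=200, patience=50,
                 learning_rate=1e-3, batch_size=32, threshold=0.5,
                 validation_fraction=0.25, random_state=0):
        self.conv_kernel = conv_kernel
        self.conv_channels = conv_channels
        self.pool_size = pool_size
        self.ff_dims = ff_dims
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _model_config(self, input_length: int) -> ModelConfig:
        return ModelConfig.cnn_mlp(
            input_length=input_length,
            conv_kernel=self.conv_kernel,
            conv_channels=self.conv_channels,
            pool_size=self.pool_size,
            ff_dims=tuple(self.ff_dims),
        )


class CNNKANClassifier(_BaseCNNClassifier):
    """Conv + max-pool + channel-average + Kolmogorov-Arnold head.

    The two KAN layers [features -> width -> 1] carry learnable B-spline
    edge activations with ``kan_grid`` intervals of degree ``kan_degree``
    over ``kan_domain``; defaults follow the selected setting grid 3,
    order 5, width 80.
    """

    _family = "cnn_kan"

    def __init__(self, conv_kernel=5, conv_channels=5, pool_size=4,
                 kan_grid=3, kan_degree=5, kan_width=80, kan_domain=(-1.0, 1.0),
                 max_epochs=200, patience=50, learning_rate=1e-3,
                 batch_size=32, threshold=0.5, validation_fraction=0.25,
                 random_state=0):
        self.conv_kernel = conv_kernel
        self.conv_channels = conv_channels
        self.pool_size = pool_size
        self.kan_grid = kan_grid
        self.kan_degree = kan_degree
        self.kan_width = kan_width
        self.kan_domain = kan_domain
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _model_config(self, input_length: int) -> ModelConfig:
        lo, hi = self.kan_domain
        return ModelConfig.cnn_kan(
            input_length=input_length,
            conv_kernel=self.conv_kernel,
            conv_channels=self.conv_channels,
            pool_size=self.pool_size,
            kan_spec=SplineSpec(self.kan_grid, self.kan_degree, lo, hi),
            kan_width=self.kan_width,
        )
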