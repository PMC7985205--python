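"""Neural inversion of the slab simulation: moments -> (n, mu_s', mu_a).

The inverse map is a small fully connected network [21, x, x, x, 3] (three
equal ReLU hidden layers, linear output) trained by Adam on mean-squared
error. Targets are n, log10(mu_s') and log10(mu_a), each min-max normalized
to [0, 1] over the training split; the input moments span many decades, so
they are compressed by a sign-preserving log10 and then min-max scaled per
feature over the training split. Predictions are pushed back
through the inverse transforms, so mu_s' and mu_a come out strictly
positive on the linear mm^-1 scale.

The module follows the model/results idiom: :class:`MomentInversion` holds
the training data, its :meth:`~MomentInversion.fit` returns a
:class:`MomentInversionResults` carrying the weights, scalers, loss history
and prediction/persistence methods. Training is delegated to
scikit-learn's multilayer-perceptron regressor; the fitted network is
stored as plain arrays and the forward pass at prediction time is
evaluated directly from those, so a saved model is a self-describing JSON
document with no framework-private state.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .featurize import FeatureVector, moment_labels
from .montecarlo import InvalidParameterError, OpticalProperties

__all__ = [
    "MinMaxScaler",
    "TargetScaler",
    "normalize_targets",
    "denormalize_targets",
    "MomentInversion",
    "MomentInversionResults",
    "train_inverse_model",
    "predict",
    "signed_log",
    "TARGET_LABELS",
]

TARGET_LABELS = ("n", "mu_s_prime", "mu_a")


def signed_log(x: np.ndarray) -> np.ndarray:
    """Sign-preserving log compression sign(x) * log10(1 + |x|)."""
    return np.sign(x) * np.log10(1.0 + np.abs(x))


@dataclass
class MinMaxScaler:
    """Per-column affine map to [0, 1]: x -> (x - min) / (max - min).

    Fitted on the training split only. A constant column would make the
    map degenerate, so ``fit`` widens it symmetrically by ``pad_constant``
    on each side (the column then maps to 0.5); constructing a scaler
    directly with min >= max raises.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.mins >= self.maxs):
            raise InvalidParameterError("degenerate scaler: require min < max per column")

    @classmethod
    def fit(cls, X: np.ndarray, pad_constant: float = 0.5) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        mins = X.min(axis=0)
        maxs = X.max(axis=0)
        constant = mins == maxs
        if np.any(constant):
            warnings.warn(
                f"{int(constant.sum())} constant column(s); "
                f"widening their range by +/-{pad_constant}",
                RuntimeWarning,
                stacklevel=2,
            )
            mins = np.where(constant, mins - pad_constant, mins)
            maxs = np.where(constant, maxs + pad_constant, maxs)
        return cls(mins=mins, maxs=maxs)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mins) / (self.maxs - self.mins)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * (self.maxs - self.mins) + self.mins

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        return cls(mins=np.array(d["mins"]), maxs=np.array(d["maxs"]))


@dataclass
class TargetScaler:
    """Min-max normalization of (n, log10(mu_s'), log10(mu_a)).

    ``transform`` takes linear-scale targets, applies log10 to the two
    coefficients, then maps each column to [0, 1]; ``inverse_transform``
    undoes both steps exactly.
    """

    scaler: MinMaxScaler

    @classmethod
    def fit(cls, targets_linear: np.ndarray) -> "TargetScaler":
        # A constant target column carries no dynamic range; a narrow pad
        # keeps the inverse map's sensitivity to network noise equally
        # narrow, so a degenerate fit still recovers the constant closely.
        return cls(scaler=MinMaxScaler.fit(cls._to_log(targets_linear), pad_constant=0.01))

    @staticmethod
    def _to_log(targets_linear: np.ndarray) -> np.ndarray:
        t = np.array(targets_linear, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3:
            raise InvalidParameterError("targets must be an (n, 3) array of (n, mu_s', mu_a)")
        if np.any(t[:, 1:] <= 0.0):
            raise InvalidParameterError("mu_s' and mu_a must be positive for the log transform")
        out = t.copy()
        out[:, 1] = np.log10(t[:, 1])
        out[:, 2] = np.log10(t[:, 2])
        return out

    def transform(self, targets_linear: np.ndarray) -> np.ndarray:
        return self.scaler.transform(self._to_log(targets_linear))

    def inverse_transform(self, normalized: np.ndarray) -> np.ndarray:
        out = self.scaler.inverse_transform(np.asarray(normalized, dtype=float))
        out = np.atleast_2d(out).copy()
        out[:, 1] = 10.0 ** out[:, 1]
        out[:, 2] = 10.0 ** out[:, 2]
        return out

    def to_dict(self) -> dict:
        return self.scaler.to_dict()

    @classmethod
    def from_dict(cls, d: dict) -> "TargetScaler":
        return cls(scaler=MinMaxScaler.from_dict(d))


def normalize_targets(
    truth: Union[OpticalProperties, np.ndarray], scaler: TargetScaler
) -> np.ndarray:
    """Normalize one or many (n, mu_s', mu_a) triples to [0, 1]^3."""
    if isinstance(truth, OpticalProperties):
        arr = np.array([[truth.n, truth.mu_s_prime, truth.mu_a]])
        return scaler.transform(arr)[0]
    arr = np.atleast_2d(np.asarray(truth, dtype=float))
    out = scaler.transform(arr)
    return out[0] if np.asarray(truth).ndim == 1 else out


def denormalize_targets(normalized: np.ndarray, scaler: TargetScaler) -> np.ndarray:
    """Inverse of :func:`normalize_targets`, back to the linear scale."""
    arr = np.atleast_2d(np.asarray(normalized, dtype=float))
    out = scaler.inverse_transform(arr)
    return out[0] if np.asarray(normalized).ndim == 1 else out


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class MomentInversion:
    """Inverse model specification: moment features paired with truths.

    Parameters
    ----------
    features : (n_records, n_features) array
        Moment vectors in canonical order.
    targets : (n_records, 3) array
        Linear-scale truths (n, mu_s_prime, mu_a).
    feature_labels : sequence of str, optional
        Column names; defaults to the canonical moment labels when the
        width matches 21.
    """

    def __init__(
        self,
        features: np.ndarray,
        targets: np.ndarray,
        feature_labels: Optional[Sequence[str]] = None,
    ) -> None:
        self.features = np.asarray(features, dtype=float)
        self.targets = np.asarray(targets, dtype=float)
        if self.features.ndim != 2:
            raise InvalidParameterError("features must be a 2-D array")
        if self.targets.shape != (self.features.shape[0], 3):
            raise InvalidParameterError("targets must be (n_records, 3)")
        if not np.all(np.isfinite(self.features)):
            bad = np.where(~np.isfinite(self.features).all(axis=1))[0]
            raise InvalidParameterError(
                f"non-finite features in records {bad[:20].tolist()}"
                + ("..." if bad.size > 20 else "")
            )
        if feature_labels is None and self.features.shape[1] == 21:
            feature_labels = moment_labels(5)
        self.feature_labels = list(feature_labels) if feature_labels is not None else None

    @classmethod
    def from_dataset(cls, dataset, split: Optional[str] = "train") -> "MomentInversion":
        """Build from a :class:`~tissueoptics.dataset.Dataset` split."""
        return cls(
            features=dataset.features(split),
            targets=dataset.targets(split),
            feature_labels=dataset.feature_columns,
        )

    def fit(
        self,
        hidden_size: int = 150,
        n_hidden_layers: int = 3,
        epochs: int = 5000,
        seed: int = 0,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        solver: str = "adam",
        signed_log_features: bool = True,
        verbose: bool = False,
    ) -> "MomentInversionResults":
        """Train the [n_features, x, ..., x, 3] network and return results.

        Runs the full epoch budget without early stopping; with a fixed
        seed the loss history is reproducible. ``solver='lbfgs'`` is useful
        for memorizing tiny datasets exactly.
        """
        from sklearn.neural_network import MLPRegressor

        if hidden_size < 1 or epochs < 1:
            raise InvalidParameterError("hidden_size and epochs must be >= 1")
        X = self.features
        if signed_log_features:
            X = signed_log(X)
        feature_scaler = MinMaxScaler.fit(X)
        target_scaler = TargetScaler.fit(self.targets)
        Xs = feature_scaler.transform(X)
        ys = target_scaler.transform(self.targets)

        common = dict(
            hidden_layer_sizes=(hidden_size,) * n_hidden_layers,
            activation="relu",
            random_state=seed,
            max_iter=epochs,
            verbose=verbose,
        )
        if solver == "adam":
            reg = MLPRegressor(
                solver="adam",
                alpha=0.0,
                batch_size=min(batch_size, Xs.shape[0]),
                learning_rate_init=learning_rate,
                shuffle=True,
                tol=0.0,
                n_iter_no_change=epochs + 1,
                early_stopping=False,
                **common,
            )
        elif solver == "lbfgs":
            reg = MLPRegressor(solver="lbfgs", alpha=0.0, tol=1e-12, **common)
        else:
            raise InvalidParameterError(f"solver must be adam|lbfgs, got {solver!r}")
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", category=ConvergenceWarning)
            reg.fit(Xs, ys)

        layer_sizes = [Xs.shape[1]] + [hidden_size] * n_hidden_layers + [3]
        return MomentInversionResults(
            layer_sizes=layer_sizes,
            weights=[np.asarray(w, dtype=float) for w in reg.coefs_],
            biases=[np.asarray(b, dtype=float) for b in reg.intercepts_],
            feature_scaler=feature_scaler,
            target_scaler=target_scaler,
            signed_log_features=signed_log_features,
            loss_curve=[float(v) for v in getattr(reg, "loss_curve_", [])],
            epochs=epochs,
            seed=seed,
            solver=solver,
            model=self,
        )


@dataclass
class MomentInversionResults:
    """Fitted inverse network: weights, scalers and training history.

    ``predict`` evaluates the stored network directly (ReLU hidden layers,
    linear output) and returns linear-scale (n, mu_s', mu_a); ``save`` and
    ``load`` round-trip the full state through JSON bit-exactly.
    """

    layer_sizes: List[int]
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    feature_scaler: MinMaxScaler
    target_scaler: TargetScaler
    signed_log_features: bool = False
    loss_curve: List[float] = field(default_factory=list)
    epochs: int = 0
    seed: int = 0
    solver: str = "adam"
    model: Optional[MomentInversion] = None

    @property
    def hidden_size(self) -> int:
        return self.layer_sizes[1]

    @property
    def final_loss(self) -> float:
        return self.loss_curve[-1] if self.loss_curve else float("nan")

    def _validate_features(self, features) -> np.ndarray:
        if isinstance(features, FeatureVector):
            if not features.valid:
                raise InvalidParameterError("cannot predict from an invalid feature vector")
            features = features.values
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.layer_sizes[0]:
            raise InvalidParameterError(
                f"expected {self.layer_sizes[0]} features, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise InvalidParameterError("features contain non-finite values")
        return X

    def _forward_row(self, row: np.ndarray) -> np.ndarray:
        h = row
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = _relu(h @ W + b)
        return h @ self.weights[-1] + self.biases[-1]

    def predict_normalized(self, features) -> np.ndarray:
        """Forward pass on scaled inputs; outputs on the [0, 1] target scale.

        Rows are evaluated one at a time so batched prediction is bitwise
        identical to record-by-record prediction.
        """
        X = self._validate_features(features)
        if self.signed_log_features:
            X = signed_log(X)
        Xs = self.feature_scaler.transform(X)
        return np.stack([self._forward_row(row) for row in Xs])

    def predict(self, features) -> np.ndarray:
        """Estimate (n, mu_s' [mm^-1], mu_a [mm^-1]) for one or many records."""
        single = not isinstance(features, (FeatureVector,)) and np.asarray(features).ndim == 1
        single = single or isinstance(features, FeatureVector)
        out = self.target_scaler.inverse_transform(self.predict_normalized(features))
        return out[0] if single else out

    def summary(self) -> str:
        lines = [
            "Moment inversion network",
            "=" * 40,
            f"architecture     : {self.layer_sizes}",
            f"activation       : relu (linear output)",
            f"solver           : {self.solver}",
            f"epochs           : {self.epochs}",
            f"seed             : {self.seed}",
            f"signed-log input : {self.signed_log_features}",
            f"final train loss : {self.final_loss:.6g}",
            f"targets          : {', '.join(TARGET_LABELS)}"
            " (log10 scale for mu_s_prime, mu_a)",
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        doc = {
            "format": "tissueoptics-inverse-model",
            "version": 1,
            "layer_sizes": self.layer_sizes,
            "activation": "relu",
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_scaler": self.feature_scaler.to_dict(),
            "target_scaler": self.target_scaler.to_dict(),
            "signed_log_features": self.signed_log_features,
            "training": {
                "epochs": self.epochs,
                "seed": self.seed,
                "solver": self.solver,
                "loss_curve": self.loss_curve,
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "MomentInversionResults":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "tissueoptics-inverse-model":
            raise ValueError(f"{path} is not a serialized inverse model")
        return cls(
            layer_sizes=doc["layer_sizes"],
            weights=[np.array(w, dtype=float) for w in doc["weights"]],
            biases=[np.array(b, dtype=float) for b in doc["biases"]],
            feature_scaler=MinMaxScaler.from_dict(doc["feature_scaler"]),
            target_scaler=TargetScaler.from_dict(doc["target_scaler"]),
            signed_log_features=doc["signed_log_features"],
            loss_curve=doc["training"]["loss_curve"],
            epochs=doc["training"]["epochs"],
            seed=doc["training"]["seed"],
            solver=doc["training"]["solver"],
        )


def train_inverse_model(
    dataset,
    hidden_size: int = 150,
    epochs: int = 5000,
    seed: int = 0,
    **fit_kwargs,
) -> MomentInversionResults:
    """Convenience wrapper: fit on a dataset's training split."""
    return MomentInversion.from_dataset(dataset, split="train").fit(
        hidden_size=hidden_size, epochs=epochs, seed=seed, **fit_kwargs
    )


def predict(results: MomentInversionResults, features) -> np.ndarray:
    """Functional alias of :meth:`MomentInversionResults.predict`."""
    return results.predict(features)
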