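"""Whole-portrait neural-network classification ("face recognition" stage).

A small fully connected network is trained on the flattened metagene
portraits with class labels: pixels are standardized with training-set
statistics, a stratified 80/20 train/validation split monitors early
stopping, and the output layer is a softmax so class probabilities sum to
one. The network never feeds other stages; it probes how much subtype
information the portraits carry beyond the spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .som import Portrait

logger = logging.getLogger("lymphoscape")

__all__ = ["PortraitClassifier", "train_portrait_classifier", "predict"]


@dataclass
class PortraitClassifier:
    scaler: StandardScaler
    net: MLPClassifier
    classes: list[str]
    n_pixels: int
    hidden_sizes: tuple[int, ...]
    epochs: int
    seed: int
    validation_accuracy: float


def _portrait_matrix(portrait_list: list[Portrait]) -> np.ndarray:
    return np.array([p.pixel_values for p in portrait_list])


def train_portrait_classifier(portrait_list: list[Portrait], labels: dict[str, str],
                              hidden_sizes: tuple[int, ...] = (64,),
                              epochs: int = 200, seed: int = 0,
                              patience: int = 10,
                              learning_rate: float = 1e-3) -> PortraitClassifier:
    """Train the portrait classifier (mini-batch cross-entropy, early
    stopping on a stratified validation split). Deterministic given seed."""
    X = _portrait_matrix(portrait_list)
    y = np.array([labels[p.sample_id] for p in portrait_list])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 10]
    if small:
        logger.warning("classes with fewer than 10 samples: %s", small)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=0.2, random_state=seed, stratify=y)
    scaler = StandardScaler().fit(X_tr)
    net = MLPClassifier(
        hidden_layer_sizes=hidden_sizes, activation="relu", solver="adam",
        learning_rate_init=learning_rate, max_iter=epochs, batch_size=min(32, len(X_tr)),
        early_stopping=True, n_iter_no_change=patience, validation_fraction=0.15,
        random_state=seed,
    )
    net.fit(scaler.transform(X_tr), y_tr)
    val_acc = float(net.score(scaler.transform(X_val), y_val))
    return PortraitClassifier(scaler=scaler, net=net, classes=list(net.classes_),
                              n_pixels=X.shape[1], hidden_sizes=tuple(hidden_sizes),
                              epochs=epochs, seed=seed, validation_accuracy=val_acc)


def predict(classifier: PortraitClassifier,
            portrait_list: list[Portrait]) -> tuple[np.ndarray, list[str]]:
    """Class probabilities (rows summing to 1) and argmax labels."""
    X = _portrait_matrix(portrait_list)
    if X.shape[1] != classifier.n_pixels:
        raise ValueError(
            f"portrait length {X.shape[1]} does not match the input layer "
            f"({classifier.n_pixels} pixels)")
    proba = classifier.net.predict_proba(classifier.scaler.transform(X))
    labels = [classifier.classes[i] for i in np.argmax(proba, axis=1)]
    return proba, labels
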