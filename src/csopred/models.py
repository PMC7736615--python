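"""The five classifier families for sulphenylation-site prediction.

Neural families (``lstm_we``, ``cnn1d_we``, ``cnn2d_pssm``) run on the
in-package numpy engine (:mod:`csopred.nn`); ``rf`` and ``svm`` wrap
scikit-learn.  All families share one interface: build a :class:`ModelSpec`,
``train`` it, then ``predict_scores`` to get modification probabilities in
[0, 1].

Architectures:

* ``lstm_we`` — integer input, word embedding (4-dim default, 5 for the
  Arabidopsis variant), an LSTM with 32 hidden units, one ReLU dense
  sublayer (16 default, 32 for Arabidopsis), sigmoid output.
* ``cnn1d_we`` — same head and tail, with an unpadded width-9 convolution
  (22 filters default, 20 for Arabidopsis) and global max pooling in place
  of the LSTM.
* ``cnn2d_pssm`` — 20x20 PSSM images through a 5x5 convolution with 15
  filters and stride 1, 2x2 max pooling, flatten, dense, sigmoid.
* ``rf`` — 580 trees (grid-searched default).
* ``svm`` — RBF kernel; features not already in [0, 1] are min-max
  normalised on the training data.

Training follows the shared protocol: Adam on binary cross-entropy,
batch size 512, early stopping after 50 epochs without training-loss
improvement, best-by-training-loss checkpoint restored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import nn
from .alphabet import ALPHABET
from .dataio import Segment
from .encoders import (
    FeatureMatrix,
    PssmModel,
    encode_aaindex,
    encode_binary,
    encode_cksaap,
    encode_eaac,
    encode_num,
    encode_pssm,
    encode_pssm_images,
)

NEURAL_FAMILIES = {"lstm_we", "cnn1d_we", "cnn2d_pssm"}
SKLEARN_FAMILIES = {"rf", "svm"}

DEFAULT_TRAINING = {
    "batch_size": 512,
    "max_epochs": 500,
    "patience": 50,
    "learning_rate": 1e-3,
}


@dataclass
class ModelSpec:
    family: str
    encoding: str
    arch: dict = dc_field(default_factory=dict)
    training: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        known = NEURAL_FAMILIES | SKLEARN_FAMILIES
        if self.family not in known:
            raise ValueError(f"unknown family {self.family!r}; expected one of {sorted(known)}")
        for key, value in {**self.arch, **self.training}.items():
            if isinstance(value, (int, float)) and not key.startswith("dropout") and value <= 0:
                raise ValueError(f"parameter {key!r} must be positive, got {value}")


@dataclass
class TrainedModel:
    spec: ModelSpec
    backend: object  # nn.Network or fitted sklearn estimator
    history: dict = dc_field(default_factory=dict)
    normalization: tuple[np.ndarray, np.ndarray] | None = None
    thresholds: dict = dc_field(default_factory=dict)  # specificity level -> threshold
    artifacts: dict = dc_field(default_factory=dict)  # e.g. fitted PssmModel


def build_lstm_we(
    L: int = 33,
    embedding_dim: int = 4,
    lstm_units: int = 32,
    dense_units: int = 16,
    dropout: float = 0.2,
    **training,
) -> ModelSpec:
    """Recurrent word-embedding classifier (4/16 human defaults; pass
    ``embedding_dim=5, dense_units=32`` for the Arabidopsis variant)."""
    return ModelSpec(
        "lstm_we",
        "num",
        {
            "L": L,
            "embedding_dim": embedding_dim,
            "lstm_units": lstm_units,
            "dense_units": dense_units,
            "dropout": dropout,
        },
        {**DEFAULT_TRAINING, **training},
    )


def build_cnn1d_we(
    L: int = 33,
    filters: int = 22,
    kernel_size: int = 9,
    dense_units: int = 16,
    embedding_dim: int = 4,
    dropout: float = 0.2,
    **training,
) -> ModelSpec:
    """1-D convolutional word-embedding classifier (22 filters human
    default, 20 for Arabidopsis; kernel width 9)."""
    return ModelSpec(
        "cnn1d_we",
        "num",
        {
            "L": L,
            "embedding_dim": embedding_dim,
            "filters": filters,
            "kernel_size": kernel_size,
            "dense_units": dense_units,
            "dropout": dropout,
        },
        {**DEFAULT_TRAINING, **training},
    )


def build_cnn2d_pssm(
    filters: int = 15,
    kernel_size: int = 5,
    pool_size: int = 2,
    dense_units: int = 16,
    dropout: float = 0.2,
    image_mode: str = "onehot",
    **training,
) -> ModelSpec:
    """2-D convolutional classifier on 20x20 PSSM images."""
    return ModelSpec(
        "cnn2d_pssm",
        "pssm_image",
        {
            "filters": filters,
            "kernel_size": kernel_size,
            "pool_size": pool_size,
            "dense_units": dense_units,
            "dropout": dropout,
            "image_mode": image_mode,
        },
        {**DEFAULT_TRAINING, **training},
    )


def build_rf(n_trees: int = 580, encoding: str = "eaac", **arch) -> ModelSpec:
    return ModelSpec("rf", encoding, {"n_trees": n_trees, **arch})


def build_svm(kernel: str = "rbf", C: float = 1.0, gamma="scale",
              encoding: str = "binary") -> ModelSpec:
    return ModelSpec("svm", encoding, {"kernel": kernel, "C": C, "gamma": gamma})


def n_parameters_lstm_we(embedding_dim: int, lstm_units: int, dense_units: int,
                         vocab: int = 21) -> int:
    """Closed-form trainable-parameter count of the recurrent architecture."""
    e, u, d = embedding_dim, lstm_units, dense_units
    return vocab * e + 4 * u * (e + u + 1) + (u * d + d) + (d + 1)


def _build_network(spec: ModelSpec, rng: np.random.Generator) -> nn.Network:
    a = spec.arch
    if spec.family == "lstm_we":
        e, u, d = a["embedding_dim"], a["lstm_units"], a["dense_units"]
        return nn.Network([
            nn.Embedding(21, e, rng),
            nn.LSTM(e, u, rng),
            nn.Dropout(a.get("dropout", 0.0), rng),
            nn.Dense(u, d, rng, relu=True),
            nn.Dense(d, 1, rng),
        ])
    if spec.family == "cnn1d_we":
        e, f, k, d = a["embedding_dim"], a["filters"], a["kernel_size"], a["dense_units"]
        return nn.Network([
            nn.Embedding(21, e, rng),
            nn.Conv1D(e, f, k, rng, relu=True),
            nn.GlobalMaxPool1D(),
            nn.Dropout(a.get("dropout", 0.0), rng),
            nn.Dense(f, d, rng, relu=True),
            nn.Dense(d, 1, rng),
        ])
    if spec.family == "cnn2d_pssm":
        f, k, p, d = a["filters"], a["kernel_size"], a["pool_size"], a["dense_units"]
        side = (20 - k + 1) // p
        return nn.Network([
            nn.Conv2D(1, f, k, rng, relu=True),
            nn.MaxPool2D(p),
            nn.Flatten(),
            nn.Dropout(a.get("dropout", 0.0), rng),
            nn.Dense(side * side * f, d, rng, relu=True),
            nn.Dense(d, 1, rng),
        ])
    raise ValueError(f"{spec.family!r} is not a neural family")


def prepare_inputs(spec: ModelSpec, X) -> np.ndarray:
    """Normalise the many accepted input forms to the array a family expects."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    elif isinstance(X, (list, tuple)) and X and isinstance(X[0], (Segment, str)):
        if spec.encoding != "num":
            raise ValueError(
                f"family {spec.family!r} with encoding {spec.encoding!r} needs "
                "pre-encoded features, not raw segments"
            )
        X = encode_num(X).values
    X = np.asarray(X)
    if spec.family == "cnn2d_pssm":
        if X.ndim == 3:
            X = X[..., None]
        if X.shape[1:3] != (20, 20):
            raise ValueError(f"expected 20x20 images, got {X.shape[1:3]}")
    return X


def train(spec: ModelSpec, X, y, seed: int = 0) -> TrainedModel:
    """Fit one classifier.  ``X`` may be segments (word-embedding families),
    a FeatureMatrix, a plain array, or a stack of PSSM images."""
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = prepare_inputs(spec, X)
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)}")

    if spec.family in NEURAL_FAMILIES:
        rng = np.random.default_rng(seed)
        net = _build_network(spec, rng)
        history = nn.fit(
            net,
            X,
            y,
            batch_size=spec.training.get("batch_size", 512),
            max_epochs=spec.training.get("max_epochs", 500),
            patience=spec.training.get("patience", 50),
            learning_rate=spec.training.get("learning_rate", 1e-3),
            seed=seed,
        )
        return TrainedModel(spec, net, history)

    if spec.family == "rf":
        clf = RandomForestClassifier(
            n_estimators=spec.arch["n_trees"], random_state=seed, n_jobs=1
        )
        clf.fit(X, y)
        return TrainedModel(spec, clf)

    # svm: min-max normalise features not already within [0, 1]
    norm = None
    Xf = X.astype(np.float64)
    if Xf.size and (Xf.min() < 0.0 or Xf.max() > 1.0):
        lo, hi = Xf.min(axis=0), Xf.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        norm = (lo, span)
        Xf = (Xf - lo) / span
    clf = SVC(
        kernel=spec.arch["kernel"], C=spec.arch["C"], gamma=spec.arch["gamma"],
        random_state=seed,
    )
    clf.fit(Xf, y)
    return TrainedModel(spec, clf, normalization=norm)


def predict_scores(model, X, batch_size: int = 1024) -> np.ndarray:
    """Modification probability (or monotone score in [0, 1]) per row."""
    if isinstance(model, BalancedEnsemble):
        return model.predict_scores(X, batch_size=batch_size)
    spec = model.spec
    X = prepare_inputs(spec, X)
    if spec.family in NEURAL_FAMILIES:
        return model.backend.predict_proba(X, batch_size=batch_size)
    if spec.family == "rf":
        return model.backend.predict_proba(X)[:, 1]
    Xf = X.astype(np.float64)
    if model.normalization is not None:
        lo, span = model.normalization
        Xf = (Xf - lo) / span
    # monotone squashing of the decision margin; rank metrics are unaffected
    return nn.sigmoid(model.backend.decision_function(Xf))


@dataclass
class BalancedEnsemble:
    """Average of sub-classifiers, each trained on all positives plus one
    part of the negatives (1:1 ratio when negatives ~ n_parts x positives)."""

    spec: ModelSpec
    submodels: list[TrainedModel]
    thresholds: dict = dc_field(default_factory=dict)
    artifacts: dict = dc_field(default_factory=dict)

    def predict_scores(self, X, batch_size: int = 1024) -> np.ndarray:
        scores = [predict_scores(m, X, batch_size=batch_size) for m in self.submodels]
        return np.mean(scores, axis=0)


def train_balanced_ensemble(
    spec: ModelSpec, X_pos, X_neg, n_parts: int = 5, seed: int = 0
) -> BalancedEnsemble:
    """Split the negatives into ``n_parts`` near-equal parts and train one
    sub-model per part on (all positives + that part)."""
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    X_pos = prepare_inputs(spec, X_pos)
    X_neg = prepare_inputs(spec, X_neg)
    rng = np.random.default_rng(seed)
    # assignment is random but original row order is kept within each part,
    # so a 1-part ensemble trains on exactly the same data as a single model
    parts = [np.sort(p) for p in np.array_split(rng.permutation(len(X_neg)), n_parts)]
    submodels = []
    for j, part in enumerate(parts):
        Xj = np.concatenate([X_pos, X_neg[part]])
        yj = np.concatenate([np.ones(len(X_pos)), np.zeros(len(part))])
        submodels.append(train(spec, Xj, yj, seed=seed + j))
    return BalancedEnsemble(spec, submodels)


_LAYER_STOPS = {
    "lstm_we": {"input": 0, "embedding": 1, "lstm": 2, "dense": 4},
    "cnn1d_we": {"input": 0, "embedding": 1, "conv": 2, "pooled": 3, "dense": 5},
    "cnn2d_pssm": {"input": 0, "conv": 1, "pooled": 2, "dense": 5},
}


def extract_layer_outputs(model: TrainedModel, X, layer: str) -> np.ndarray:
    """Per-sample activations at a named layer, flattened to (n, width) —
    the raw material for external 2-D embedding visualisation."""
    spec = model.spec
    if spec.family not in _LAYER_STOPS:
        raise ValueError(f"family {spec.family!r} has no inspectable layers")
    stops = _LAYER_STOPS[spec.family]
    if layer not in stops:
        raise ValueError(
            f"family {spec.family!r} has no layer {layer!r}; choose from {sorted(stops)}"
        )
    X = prepare_inputs(spec, X)
    out = model.backend.forward(X, train=False, upto=stops[layer])
    out = np.asarray(out, dtype=np.float64)
    return out.reshape(out.shape[0], -1)


# ---------------------------------------------------------------------------
# Checkpoint serialisation: meta.json + weights file, enough to reproduce
# predictions from disk.


def save_model(model: TrainedModel | BalancedEnsemble, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, BalancedEnsemble):
        meta = {
            "kind": "balanced_ensemble",
            "spec": _spec_dict(model.spec),
            "thresholds": model.thresholds,
            "n_parts": len(model.submodels),
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        _save_artifacts(model.artifacts, directory)
        for j, sub in enumerate(model.submodels):
            save_model(sub, directory / f"part{j}")
        return
    meta = {
        "kind": "model",
        "spec": _spec_dict(model.spec),
        "thresholds": model.thresholds,
        "alphabet": ALPHABET,
        "has_normalization": model.normalization is not None,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    _save_artifacts(model.artifacts, directory)
    if model.spec.family in NEURAL_FAMILIES:
        weights = {f"w{j}": w for j, w in enumerate(model.backend.get_weights())}
        np.savez(directory / "weights.npz", **weights)
    else:
        import joblib

        joblib.dump(model.backend, directory / "backend.joblib")
        if model.normalization is not None:
            np.savez(
                directory / "normalization.npz",
                lo=model.normalization[0],
                span=model.normalization[1],
            )


def load_model(directory) -> TrainedModel | BalancedEnsemble:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    spec = ModelSpec(**meta["spec"])
    thresholds = {float(k): v for k, v in meta.get("thresholds", {}).items()}
    artifacts = _load_artifacts(directory)
    if meta["kind"] == "balanced_ensemble":
        subs = [load_model(directory / f"part{j}") for j in range(meta["n_parts"])]
        return BalancedEnsemble(spec, subs, thresholds=thresholds, artifacts=artifacts)
    if spec.family in NEURAL_FAMILIES:
        net = _build_network(spec, np.random.default_rng(0))
        data = np.load(directory / "weights.npz")
        net.set_weights([data[f"w{j}"] for j in range(len(data.files))])
        model = TrainedModel(spec, net, thresholds=thresholds, artifacts=artifacts)
    else:
        import joblib

        backend = joblib.load(directory / "backend.joblib")
        norm = None
        norm_path = directory / "normalization.npz"
        if norm_path.exists():
            data = np.load(norm_path)
            norm = (data["lo"], data["span"])
        model = TrainedModel(
            spec, backend, normalization=norm, thresholds=thresholds,
            artifacts=artifacts,
        )
    return model


def _spec_dict(spec: ModelSpec) -> dict:
    return {
        "family": spec.family,
        "encoding": spec.encoding,
        "arch": spec.arch,
        "training": spec.training,
    }


def _save_artifacts(artifacts: dict, directory: Path) -> None:
    pssm = artifacts.get("pssm")
    if pssm is not None:
        np.savez(
            directory / "pssm.npz",
            pos_freq=pssm.pos_freq,
            neg_freq=pssm.neg_freq,
            t_stat=pssm.t_stat,
            p_adj=pssm.p_adj,
            score=pssm.score,
            alpha=np.array(pssm.alpha),
        )
    props = artifacts.get("aaindex")
    if props is not None:
        props.to_csv(directory / "aaindex.tsv", sep="\t")


def _load_artifacts(directory: Path) -> dict:
    artifacts: dict = {}
    pssm_path = directory / "pssm.npz"
    if pssm_path.exists():
        d = np.load(pssm_path)
        artifacts["pssm"] = PssmModel(
            d["pos_freq"], d["neg_freq"], d["t_stat"], d["p_adj"], d["score"],
            float(d["alpha"]),
        )
    aaindex_path = directory / "aaindex.tsv"
    if aaindex_path.exists():
        import pandas as pd

        artifacts["aaindex"] = pd.read_csv(aaindex_path, sep="\t", index_col=0)
    return artifacts


def encode_for(spec: ModelSpec, segments, artifacts: dict | None = None):
    """Encode segments under a spec's scheme, using fitted artifacts where the
    scheme needs them (PSSM matrices, selected AAindex properties)."""
    artifacts = artifacts or {}
    scheme = spec.encoding
    if scheme == "num":
        return encode_num(segments).values
    if scheme == "binary":
        return encode_binary(segments).values
    if scheme == "eaac":
        return encode_eaac(segments).values
    if scheme == "cksaap":
        return encode_cksaap(segments).values
    if scheme == "aaindex":
        if "aaindex" not in artifacts:
            raise ValueError("aaindex encoding requires a fitted property table artifact")
        return encode_aaindex(segments, artifacts["aaindex"]).values
    if scheme == "pssm":
        if "pssm" not in artifacts:
            raise ValueError("pssm encoding requires a fitted PssmModel artifact")
        return encode_pssm(segments, artifacts["pssm"]).values
    if scheme == "pssm_image":
        if "pssm" not in artifacts:
            raise ValueError("pssm_image encoding requires a fitted PssmModel artifact")
        return encode_pssm_images(
            segments, artifacts["pssm"], mode=spec.arch.get("image_mode", "onehot")
        )
    raise ValueError(f"unknown encoding scheme {scheme!r}")
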