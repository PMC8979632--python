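"""Per-frame probe/liver contact detection from B-mode intensity statistics.

Surface scanning only records a surface point when the transducer face has
full contact with the liver capsule.  Frames without contact show a dark or
noise-dominated band in the shallow part of the image, so five summary
statistics of the upper third of the image — minimum, maximum, mean,
standard deviation and kurtosis — separate the two states well, and a small
RBF-kernel support vector machine on standardised features makes the call.

Kurtosis uses the Fisher (excess) convention, i.e. a normal distribution
scores 0; a zero-variance (constant) upper band maps to 0 with a warning.
This convention is stored with the model so training and prediction can
never silently disagree.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ContactFeatures",
    "ContactModel",
    "TrainingConfig",
    "extract_features",
    "train_contact_model",
    "predict_contact",
    "save_contact_model",
    "load_contact_model",
    "CONTACT",
    "NO_CONTACT",
]

CONTACT: Literal["contact"] = "contact"
NO_CONTACT: Literal["no_contact"] = "no_contact"

FEATURE_NAMES = ("fmin", "fmax", "fmean", "fstd", "fkurtosis")

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ContactFeatures:
    """Intensity statistics of the upper third (rows [0, floor(H/3))) of a frame."""

    fmin: float
    fmax: float
    fmean: float
    fstd: float
    fkurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array([self.fmin, self.fmax, self.fmean, self.fstd, self.fkurtosis])


def extract_features(image: np.ndarray) -> ContactFeatures:
    """Compute the five contact features over the top floor(H/3) rows.

    The shallow band sits directly under the transducer face, where loss of
    capsule contact shows first; the lower two thirds of the image never
    influence the result.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("contact features require a non-empty 2D image")
    h = img.shape[0]
    if h < 3:
        raise ValueError(f"image height {h} < 3: no upper third to analyse")
    band = img[: h // 3].ravel()
    std = float(band.std())
    if std == 0.0:
        warnings.warn("constant upper band: kurtosis undefined, using 0", stacklevel=2)
        kurt = 0.0
    else:
        kurt = float(stats.kurtosis(band, fisher=True, bias=True))
    return ContactFeatures(
        fmin=float(band.min()),
        fmax=float(band.max()),
        fmean=float(band.mean()),
        fstd=std,
        fkurtosis=kurt,
    )


@dataclass(frozen=True)
class TrainingConfig:
    kernel: str = "rbf"
    C: float = 10.0
    gamma: str | float = "scale"
    seed: int = 0


@dataclass
class ContactModel:
    """Trained contact/no-contact classifier.

    Holds the fitted decision function explicitly — feature standardisation
    statistics plus the SVM's support vectors, dual coefficients, kernel
    parameter and intercept — so that prediction is a pure array
    computation and persistence is a plain NPZ archive.  The decision rule
    is ``contact`` iff ``f(x) > 0`` with

        f(x) = sum_i alpha_i K_rbf(x_std, sv_i) + b,   K_rbf = exp(-gamma d^2).
    """

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray   # standardised feature space
    dual_coef: np.ndarray         # (n_sv,), sign-adjusted so positive = contact
    intercept: float
    gamma: float
    config: TrainingConfig
    n_contact: int
    n_no_contact: int

    def decision_value(self, features: ContactFeatures) -> float:
        x = (features.as_array() - self.scaler_mean) / self.scaler_scale
        d2 = np.sum((self.support_vectors - x) ** 2, axis=1)
        return float(self.dual_coef @ np.exp(-self.gamma * d2) + self.intercept)

    def predict(self, features: ContactFeatures) -> str:
        return CONTACT if self.decision_value(features) > 0 else NO_CONTACT


def train_contact_model(
    features: Sequence[ContactFeatures],
    labels: Sequence[str],
    config: TrainingConfig | None = None,
) -> ContactModel:
    """Fit the contact SVM. Deterministic for fixed inputs and seed."""
    config = config or TrainingConfig()
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    y = np.asarray([str(l) for l in labels], dtype=object)
    classes = set(y.tolist())
    if classes != {CONTACT, NO_CONTACT}:
        raise ValueError(
            f"training set must contain both classes {{{CONTACT}, {NO_CONTACT}}}, "
            f"got {sorted(classes)}"
        )
    x = np.vstack([f.as_array() for f in features])
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    svc = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma,
              random_state=config.seed).fit(xs, y.astype(str))

    dual = svc.dual_coef_.ravel().astype(float)
    intercept = float(svc.intercept_[0])
    # orient the decision function so positive means "contact": libsvm's
    # sign convention depends on internal class order, so calibrate against
    # the estimator's own predictions on the training set
    def manual(vec: np.ndarray) -> float:
        d2 = np.sum((svc.support_vectors_ - vec) ** 2, axis=1)
        return float(dual @ np.exp(-svc._gamma * d2) + intercept)

    pred = svc.predict(xs)
    scores = np.array([manual(v) for v in xs])
    usable = pred[np.abs(scores) > 1e-9]
    sgn_scores = scores[np.abs(scores) > 1e-9]
    agree = np.mean((sgn_scores > 0) == (usable == CONTACT)) if usable.size else 1.0
    if agree < 0.5:
        dual, intercept = -dual, -intercept

    return ContactModel(
        scaler_mean=scaler.mean_.astype(float),
        scaler_scale=scaler.scale_.astype(float),
        support_vectors=svc.support_vectors_.astype(float),
        dual_coef=dual,
        intercept=intercept,
        gamma=float(svc._gamma),
        config=config,
        n_contact=int(np.sum(y == CONTACT)),
        n_no_contact=int(np.sum(y == NO_CONTACT)),
    )


def predict_contact(model: ContactModel, image: np.ndarray) -> str:
    """Hard contact/no-contact label for one frame under a trained model."""
    if model is None or not hasattr(model, "support_vectors"):
        raise ValueError("predict_contact requires a trained ContactModel")
    return model.predict(extract_features(image))


# ---------------------------------------------------------------------------
# Persistence: a single NPZ archive (no pickle).  Arrays hold the scaler
# statistics and the decision function; a JSON blob holds kernel parameters
# and training metadata.

def save_contact_model(model: ContactModel, path: str | Path) -> None:
    meta = {
        "format_version": _FORMAT_VERSION,
        "kernel": model.config.kernel,
        "C": model.config.C,
        "gamma_setting": model.config.gamma
        if isinstance(model.config.gamma, str) else float(model.config.gamma),
        "gamma_value": model.gamma,
        "intercept": model.intercept,
        "seed": model.config.seed,
        "n_contact": model.n_contact,
        "n_no_contact": model.n_no_contact,
        "kurtosis_convention": "fisher_excess_zero_on_constant",
        "feature_names": list(FEATURE_NAMES),
        "decision_rule": "contact iff f(x) > 0",
    }
    buf = io.BytesIO()
    np.savez(
        buf,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        scaler_mean=model.scaler_mean,
        scaler_scale=model.scaler_scale,
        support_vectors=model.support_vectors,
        dual_coef=model.dual_coef,
    )
    Path(path).write_bytes(buf.getvalue())


def load_contact_model(path: str | Path) -> ContactModel:
    with np.load(Path(path)) as arch:
        meta = json.loads(bytes(arch["meta"]).decode())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported contact model format {meta['format_version']}")
        config = TrainingConfig(
            kernel=meta["kernel"], C=meta["C"], gamma=meta["gamma_setting"], seed=meta["seed"]
        )
        return ContactModel(
            scaler_mean=arch["scaler_mean"],
            scaler_scale=arch["scaler_scale"],
            support_vectors=arch["support_vectors"],
            dual_coef=arch["dual_coef"],
            intercept=float(meta["intercept"]),
            gamma=float(meta["gamma_value"]),
            config=config,
            n_contact=meta["n_contact"],
            n_no_contact=meta["n_no_contact"],
        )
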