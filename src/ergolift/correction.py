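"""Pose-dependent error-correction models for lifting-equation parameters.

A depth-camera skeleton systematically mis-places joints as a function of
pose.  For each lifting-equation parameter x in {H, V, A} we model the
error delta_x = x(reference) - x(noisy) as a function of the noisy
skeleton's body-frame joint coordinates, using gradient boosted regression
trees with a Huber loss, and correct assessments by adding the predicted
delta to the raw estimate.

The module follows the model/results idiom: :class:`ErrorCorrectionModel`
is built from a :class:`DeltaDataset`; ``fit()`` returns an
:class:`ErrorCorrectionResults` carrying the fitted ensembles, training
metadata, a ``summary()`` table, prediction/correction methods, and
persistence.  Leave-one-subject-out validation hangs off the model as
``fit_loso()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .geometry import sequence_parameters
from .signal_prep import PairedFrame
from .skeleton import (
    JOINTS,
    MIRROR_PERMUTATION,
    N_JOINTS,
    SkeletonFrame,
    SkeletonSequence,
    sequence_to_body_frame,
    to_body_frame,
)

FEATURE_SCHEMA_VERSION = 1
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{j.value}_{ax}_body" for j in JOINTS for ax in "xyz"
)
N_FEATURES = len(FEATURE_NAMES)  # 60

DEFAULT_PARAMETERS = ("H", "V", "A")


class SchemaMismatchError(ValueError):
    """Feature schema at prediction time differs from the training schema."""


# ---------------------------------------------------------------------------
# features and error samples


def featurize(frame: SkeletonFrame) -> np.ndarray:
    """60-vector of body-frame joint coordinates in enumeration order."""
    _, body = to_body_frame(frame)
    return body.xyz.reshape(-1)


def featurize_sequence(seq: SkeletonSequence) -> np.ndarray:
    """(n, 60) feature matrix for every frame of a sequence."""
    return sequence_to_body_frame(seq).data.reshape(len(seq), -1)


def mirror_features(features: np.ndarray) -> np.ndarray:
    """Feature transform of the XZ-plane mirror: swap L/R blocks, negate Y."""
    x = np.asarray(features)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x).reshape(-1, N_JOINTS, 3)[:, MIRROR_PERMUTATION, :].copy()
    x[:, :, 1] = -x[:, :, 1]
    x = x.reshape(-1, N_FEATURES)
    return x[0] if squeeze else x


@dataclass(frozen=True)
class DeltaSample:
    """One paired-frame error sample."""

    features: np.ndarray  # (60,)
    delta: dict[str, float]  # parameter -> reference minus noisy
    subject_id: str = ""
    mirrored: bool = False


def compute_delta(
    pair: PairedFrame, parameters: Sequence[str] = DEFAULT_PARAMETERS, subject_id: str = ""
) -> DeltaSample:
    """Error sample for one aligned (noisy, reference) frame pair.

    delta_x = x(reference) - x(noisy); features come from the noisy frame
    expressed in its body-centric coordinates.
    """
    from .geometry import frame_parameters

    k = frame_parameters(pair.k_frame)
    q = frame_parameters(pair.q_frame)
    delta = {p: float(getattr(q, p) - getattr(k, p)) for p in parameters}
    return DeltaSample(features=featurize(pair.k_frame), delta=delta, subject_id=subject_id)


@dataclass
class DeltaDataset:
    """Columnar collection of error samples, grouped by subject label."""

    features: np.ndarray  # (n, 60)
    deltas: pd.DataFrame  # columns = modeled parameters
    subject: np.ndarray  # (n,) str
    mirrored: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        n = len(self.features)
        if not (len(self.deltas) == len(self.subject) == len(self.mirrored) == n):
            raise ValueError("dataset columns have inconsistent lengths")
        if self.features.shape[1] != N_FEATURES:
            raise SchemaMismatchError(
                f"expected {N_FEATURES} features, got {self.features.shape[1]}"
            )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.deltas.columns)

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.subject))

    def subset(self, mask: np.ndarray) -> "DeltaDataset":
        return DeltaDataset(
            features=self.features[mask],
            deltas=self.deltas.iloc[mask].reset_index(drop=True),
            subject=self.subject[mask],
            mirrored=self.mirrored[mask],
        )

    @classmethod
    def concat(cls, parts: Sequence["DeltaDataset"]) -> "DeltaDataset":
        nonempty = [p for p in parts if len(p)] or list(parts[:1])
        return cls(
            features=np.concatenate([p.features for p in nonempty]),
            deltas=pd.concat([p.deltas for p in nonempty], ignore_index=True),
            subject=np.concatenate([p.subject for p in nonempty]),
            mirrored=np.concatenate([p.mirrored for p in nonempty]),
        )

    def mirror_augmented(self) -> "DeltaDataset":
        """Append XZ-mirrored copies of all non-mirrored samples.

        H, V, and the unsigned A are mirror-invariant, so the deltas carry
        over unchanged; only the features transform.
        """
        base = self.subset(~self.mirrored)
        mirrored = DeltaDataset(
            features=mirror_features(base.features),
            deltas=base.deltas.copy(),
            subject=base.subject.copy(),
            mirrored=np.ones(len(base), dtype=bool),
        )
        return DeltaDataset.concat([self, mirrored])


def build_delta_dataset(
    pairs: list[PairedFrame], subject_id: str, mirror: bool = True
) -> DeltaDataset:
    """Vectorized error samples from a list of aligned frame pairs."""
    if not pairs:
        return DeltaDataset(
            features=np.empty((0, N_FEATURES)),
            deltas=pd.DataFrame(columns=list(DEFAULT_PARAMETERS)),
            subject=np.empty(0, dtype=object),
            mirrored=np.empty(0, dtype=bool),
        )
    times = np.array([p.time for p in pairs])
    rate = 1.0 / np.median(np.diff(times)) if len(times) > 1 else 30.0
    k_seq = SkeletonSequence(
        times=times, data=np.stack([p.k_frame.xyz for p in pairs]), nominal_rate=rate
    )
    q_seq = SkeletonSequence(
        times=times, data=np.stack([p.q_frame.xyz for p in pairs]), nominal_rate=rate
    )
    k_par = sequence_parameters(k_seq)
    q_par = sequence_parameters(q_seq)
    deltas = pd.DataFrame(
        {p: q_par[p].to_numpy() - k_par[p].to_numpy() for p in DEFAULT_PARAMETERS}
    )
    ds = DeltaDataset(
        features=featurize_sequence(k_seq),
        deltas=deltas,
        subject=np.full(len(pairs), subject_id, dtype=object),
        mirrored=np.zeros(len(pairs), dtype=bool),
    )
    return ds.mirror_augmented() if mirror else ds


# ---------------------------------------------------------------------------
# model / results


@dataclass(frozen=True)
class GbrtConfig:
    """Gradient-boosted-ensemble hyperparameters (one ensemble per parameter).

    ``huber_alpha`` is the quantile at which the Huber loss switches from
    quadratic to linear.  ``max_train_samples`` caps the training set by a
    seeded subsample; smooth pose-error fields do not need every frame and
    the cap keeps leave-one-subject-out sweeps tractable.
    """

    n_estimators: int = 150
    learning_rate: float = 0.05
    max_depth: int = 3
    subsample: float = 0.8
    huber_alpha: float = 0.9
    max_features: float = 0.3
    max_train_samples: int = 15000


class ErrorCorrectionModel:
    """Per-parameter error-correction model over a paired-error dataset."""

    def __init__(
        self,
        dataset: DeltaDataset,
        parameters: Sequence[str] = DEFAULT_PARAMETERS,
        config: GbrtConfig | None = None,
    ):
        if len(dataset) == 0:
            raise ValueError("cannot build a model from an empty dataset")
        missing = [p for p in parameters if p not in dataset.parameters]
        if missing:
            raise ValueError(f"dataset lacks deltas for parameters {missing}")
        self.dataset = dataset
        self.parameters = tuple(parameters)
        self.config = config or GbrtConfig()

    @classmethod
    def from_paired_sequences(
        cls,
        pairs_by_subject: dict[str, list[PairedFrame]],
        mirror: bool = True,
        **kwargs,
    ) -> "ErrorCorrectionModel":
        parts = [
            build_delta_dataset(pairs, subject_id=sid, mirror=mirror)
            for sid, pairs in pairs_by_subject.items()
        ]
        return cls(DeltaDataset.concat(parts), **kwargs)

    def _fit_one(self, X: np.ndarray, y: np.ndarray, seed: int) -> GradientBoostingRegressor:
        c = self.config
        rng = np.random.default_rng(seed)
        if c.max_train_samples and len(X) > c.max_train_samples:
            idx = rng.choice(len(X), size=c.max_train_samples, replace=False)
            X, y = X[idx], y[idx]
        est = GradientBoostingRegressor(
            loss="huber",
            alpha=c.huber_alpha,
            n_estimators=c.n_estimators,
            learning_rate=c.learning_rate,
            max_depth=c.max_depth,
            subsample=c.subsample,
            max_features=c.max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        est.fit(X, y)
        return est

    def fit(self, seed: int = 0, dataset: DeltaDataset | None = None) -> "ErrorCorrectionResults":
        """Fit one ensemble per parameter; deterministic for a given seed."""
        ds = dataset if dataset is not None else self.dataset
        if len(ds) == 0:
            raise ValueError("empty training dataset")
        estimators = {
            p: self._fit_one(ds.features, ds.deltas[p].to_numpy(), seed + i)
            for i, p in enumerate(self.parameters)
        }
        metadata = {
            "feature_schema_version": FEATURE_SCHEMA_VERSION,
            "n_features": N_FEATURES,
            "parameters": list(self.parameters),
            "training_subjects": ds.subjects,
            "n_samples": len(ds),
            "n_mirrored": int(ds.mirrored.sum()),
            "seed": seed,
            "hyperparameters": asdict(self.config),
        }
        return ErrorCorrectionResults(model=self, estimators=estimators, metadata=metadata)

    def fit_loso(self, seed: int = 0) -> "LosoReport":
        """Leave-one-subject-out evaluation of raw vs modeled errors.

        For each subject the ensembles are trained on all other subjects'
        samples (mirrored copies included) and evaluated on the held-out
        subject's non-mirrored samples.  Raw error is the measured delta;
        modeled error is the delta left after subtracting the prediction.
        """
        subjects = self.dataset.subjects
        if len(subjects) < 2:
            raise ValueError("leave-one-subject-out needs at least two subjects")
        rows = []
        per_subject_errors: dict[str, pd.DataFrame] = {}
        for i, held_out in enumerate(subjects):
            test_mask = (self.dataset.subject == held_out) & (~self.dataset.mirrored)
            train = self.dataset.subset(self.dataset.subject != held_out)
            test = self.dataset.subset(test_mask)
            results = self.fit(seed=seed + 1000 * i, dataset=train)
            predicted = results.predict(test.features)
            errors = {}
            for p in self.parameters:
                raw = test.deltas[p].to_numpy()
                modeled = raw - predicted[p].to_numpy()
                errors[p] = (raw, modeled)
                rows.append(
                    {
                        "subject": held_out,
                        "parameter": p,
                        "n_test": len(raw),
                        "raw_bias": raw.mean(),
                        "raw_variance": raw.var(),
                        "raw_mae": np.abs(raw).mean(),
                        "modeled_bias": modeled.mean(),
                        "modeled_variance": modeled.var(),
                        "modeled_mae": np.abs(modeled).mean(),
                    }
                )
            per_subject_errors[held_out] = pd.DataFrame(
                {f"{p}_{kind}": vals
                 for p, (raw, modeled) in errors.items()
                 for kind, vals in (("raw", raw), ("modeled", modeled))}
            )
        return LosoReport(table=pd.DataFrame(rows), errors=per_subject_errors)


@dataclass
class ErrorCorrectionResults:
    """Fitted error-correction ensembles plus training metadata."""

    model: ErrorCorrectionModel | None
    estimators: dict[str, GradientBoostingRegressor]
    metadata: dict

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.metadata["parameters"])

    def _check_schema(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.metadata["n_features"]:
            raise SchemaMismatchError(
                f"model expects {self.metadata['n_features']} features, "
                f"got {features.shape[1]}"
            )
        return features

    def predict(self, features: np.ndarray) -> pd.DataFrame:
        """Predicted deltas (reference minus noisy) for feature rows."""
        X = self._check_schema(features)
        return pd.DataFrame({p: est.predict(X) for p, est in self.estimators.items()})

    def correct_sequence(self, seq: SkeletonSequence, hand_anchor: str = "wrist") -> pd.DataFrame:
        """Raw and corrected per-frame parameter series for a noisy sequence.

        corrected_x = raw_x + predicted delta_x.
        """
        raw = sequence_parameters(seq, hand_anchor=hand_anchor)
        predicted = self.predict(featurize_sequence(seq))
        out = raw.copy()
        for p in self.parameters:
            out[f"{p}_corrected"] = raw[p] + predicted[p]
        return out

    def summary(self) -> str:
        """Plain-text summary table of the fitted model."""
        meta = self.metadata
        lines = [
            "Error-correction model (gradient boosted trees, Huber loss)",
            "=" * 60,
            f"feature schema:     v{meta['feature_schema_version']} "
            f"({meta['n_features']} body-frame joint coordinates)",
            f"training subjects:  {', '.join(meta['training_subjects'])}",
            f"training samples:   {meta['n_samples']} "
            f"({meta['n_mirrored']} mirrored)",
            f"seed:               {meta['seed']}",
            "hyperparameters:    "
            + ", ".join(f"{k}={v}" for k, v in meta["hyperparameters"].items()),
            "-" * 60,
            f"{'parameter':<12}{'in-sample MAE':>16}{'units':>10}",
        ]
        units = {"H": "cm", "V": "cm", "A": "deg"}
        if self.model is not None:
            ds = self.model.dataset
            pred = self.predict(ds.features)
            for p in self.parameters:
                mae = float(np.abs(ds.deltas[p].to_numpy() - pred[p].to_numpy()).mean())
                lines.append(f"{p:<12}{mae:>16.3f}{units.get(p, ''):>10}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Persist estimators (joblib) plus a JSON metadata sidecar."""
        path = Path(path)
        joblib.dump({"estimators": self.estimators, "metadata": self.metadata}, path)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(self.metadata, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ErrorCorrectionResults":
        blob = joblib.load(path)
        meta = blob["metadata"]
        if meta.get("feature_schema_version") != FEATURE_SCHEMA_VERSION:
            raise SchemaMismatchError(
                f"model was trained with feature schema "
                f"v{meta.get('feature_schema_version')}, "
                f"this package uses v{FEATURE_SCHEMA_VERSION}"
            )
        return cls(model=None, estimators=blob["estimators"], metadata=meta)


@dataclass
class LosoReport:
    """Leave-one-subject-out raw-vs-modeled error comparison."""

    table: pd.DataFrame  # one row per (held-out subject, parameter)
    errors: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> str:
        cols = [
            "subject", "parameter", "n_test",
            "raw_bias", "raw_variance", "raw_mae",
            "modeled_bias", "modeled_variance", "modeled_mae",
        ]
        return self.table[cols].to_string(index=False, float_format=lambda v: f"{v:8.3f}")

    def improved(self, metric: str = "variance") -> pd.Series:
        """Boolean per (subject, parameter): did modeling reduce the metric?"""
        return self.table[f"modeled_{metric}"] < self.table[f"raw_{metric}"]

    def plot_error_boxes(self, parameter: str = "H", ax=None):
        """Box plots of raw vs modeled errors per subject for one parameter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.5 * len(self.errors) + 2, 4))
        data, labels = [], []
        for subject, df in self.errors.items():
            data.extend([df[f"{parameter}_raw"], df[f"{parameter}_modeled"]])
            labels.extend([f"{subject}\nraw", f"{subject}\nmodeled"])
        ax.boxplot(data, tick_labels=labels, showfliers=False)
        ax.axhline(0.0, color="gray", lw=0.8)
        units = {"H": "cm", "V": "cm", "A": "deg"}
        ax.set_ylabel(f"{parameter} error ({units.get(parameter, '')})")
        ax.set_title(f"{parameter}: raw vs modeled error by held-out subject")
        return ax


# ---------------------------------------------------------------------------
# functional wrappers


def train_error_model(
    dataset: DeltaDataset, config: GbrtConfig | None = None, seed: int = 0
) -> ErrorCorrectionResults:
    return ErrorCorrectionModel(dataset, config=config).fit(seed=seed)


def apply_correction(results: ErrorCorrectionResults, seq: SkeletonSequence) -> pd.DataFrame:
    return results.correct_sequence(seq)


def loso_evaluate(
    dataset: DeltaDataset, config: GbrtConfig | None = None, seed: int = 0
) -> LosoReport:
    return ErrorCorrectionModel(dataset, config=config).fit_loso(seed=seed)
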