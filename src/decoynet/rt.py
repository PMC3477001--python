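"""Retention-time prediction and RT p-values.

A peptide's chromatographic retention time is largely determined by its
amino-acid composition (hydrophobic residues elute later on reversed-phase
columns).  The pipeline's first pass at epsilon = 0 yields a set of
near-certain identifications; their sequences and observed retention times
train a linear composition model, and the studentised deviation between
each PSM's observed and predicted RT is converted into a two-sided Gaussian
p-value — the sixth quality feature.  A genuine hit elutes near its
predicted time (p near uniform); a wrong assignment's predicted time is
unrelated to its observed one, concentrating its p-values near zero.

RT prediction is deliberately a pluggable, simple component: any regressor
mapping sequence to seconds can stand behind the same module boundary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special
from sklearn.base import BaseEstimator, RegressorMixin

from .psm import PSMRecord

__all__ = [
    "AMINO_ACIDS",
    "InsufficientRTError",
    "RTTrainingSet",
    "RetentionTimeRegressor",
    "build_rt_training_set",
    "fit_rt_model",
    "rt_pvalue",
    "strip_modifications",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_MOD_RE = re.compile(r"\[[^\]]*\]")

#: smallest reported p-value (guards the zero-residual-scale degenerate case)
P_FLOOR = 1e-300
#: ridge penalty applied when the design matrix is rank-deficient
RIDGE_PENALTY = 1e-6
#: minimum number of unique training sequences
MIN_TRAINING_PEPTIDES = 10


class InsufficientRTError(ValueError):
    """Raised when fewer than 10 unique confident peptides are available."""


def strip_modifications(peptide: str) -> str:
    """Remove bracketed modification annotations, e.g. 'ALS[p]PK' -> 'ALSPK'."""
    return _MOD_RE.sub("", peptide)


@dataclass(frozen=True)
class RTTrainingSet:
    """Unique (unmodified sequence, mean observed RT in seconds) pairs."""

    sequences: tuple[str, ...]
    rts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.rts):
            raise ValueError("sequences and rts must align")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("training sequences must be unique")
        for s in self.sequences:
            if not s or any(a not in _AA_INDEX for a in s):
                raise ValueError(f"invalid amino-acid sequence {s!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sequence\trt_observed_s\n")
            for s, t in zip(self.sequences, self.rts):
                fh.write(f"{s}\t{t!r}\n")


def build_rt_training_set(accepted: Sequence[PSMRecord]) -> RTTrainingSet:
    """Training pairs from the confidently accepted PSMs of an eps=0 pass.

    Modifications are stripped; duplicate sequences collapse to their mean
    observed RT.

    Raises
    ------
    InsufficientRTError
        With fewer than 10 unique sequences (too little signal to fit a
        composition model, mirroring the removal of datasets with fewer
        than 10 correct assignments).
    """
    sums: dict[str, list[float]] = {}
    order: list[str] = []
    for r in accepted:
        seq = strip_modifications(r.peptide)
        if seq not in sums:
            sums[seq] = []
            order.append(seq)
        sums[seq].append(r.rt_observed_s)
    if len(order) < MIN_TRAINING_PEPTIDES:
        raise InsufficientRTError(
            f"insufficient RT training data: {len(order)} unique peptides "
            f"(need >= {MIN_TRAINING_PEPTIDES})"
        )
    return RTTrainingSet(
        sequences=tuple(order),
        rts=tuple(float(np.mean(sums[s])) for s in order),
    )


def _design(sequences: Sequence[str]) -> np.ndarray:
    """Columns: 20 amino-acid counts, sequence length, intercept."""
    X = np.zeros((len(sequences), 22))
    for i, seq in enumerate(sequences):
        for a in seq:
            X[i, _AA_INDEX[a]] += 1.0
        X[i, 20] = len(seq)
        X[i, 21] = 1.0
    return X


class RetentionTimeRegressor(RegressorMixin, BaseEstimator):
    """Linear RT model on amino-acid counts plus sequence length.

    Length equals the sum of the residue counts, so the design matrix is
    rank-deficient by construction and the fit regularises all
    non-intercept coefficients with a minimal ridge penalty (1e-6); the
    identifiable quantities are the per-residue effective coefficients
    (count + length) and the predictions.  The residual scale is the
    standard deviation of training residuals with the fitted rank removed
    from the degrees of freedom.
    """

    def fit(self, sequences: Sequence[str], rts: Sequence[float]):
        X = _design(sequences)
        y = np.asarray(rts, dtype=float)
        rank = np.linalg.matrix_rank(X)
        p = X.shape[1]
        if rank < p:
            # augmented least squares: || y - X b ||^2 + RIDGE * || b_1..21 ||^2
            # (intercept unpenalised); numerically stable for the singular design
            aug = np.sqrt(RIDGE_PENALTY) * np.eye(p)[:21]
            A = np.vstack([X, aug])
            b = np.concatenate([y, np.zeros(21)])
            beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        else:  # pragma: no cover - unreachable with this design
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - rank, 1)
        self.coef_counts_ = beta[:20]
        self.coef_length_ = float(beta[20])
        self.intercept_ = float(beta[21])
        self.residual_scale_ = float(np.sqrt((resid**2).sum() / dof))
        self.n_training_ = len(y)
        return self

    @property
    def effective_coef_(self) -> np.ndarray:
        """Identifiable per-residue contribution: count + length coefficient."""
        return self.coef_counts_ + self.coef_length_

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        beta = np.concatenate(
            (self.coef_counts_, [self.coef_length_, self.intercept_])
        )
        return _design(sequences) @ beta

    def predict_one(self, sequence: str) -> float:
        return float(self.predict([sequence])[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "amino_acids": AMINO_ACIDS,
                "coef_counts": self.coef_counts_.tolist(),
                "coef_length": self.coef_length_,
                "intercept": self.intercept_,
                "residual_scale": self.residual_scale_,
                "n_training": self.n_training_,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RetentionTimeRegressor":
        doc = json.loads(text)
        model = cls()
        model.coef_counts_ = np.array(doc["coef_counts"])
        model.coef_length_ = doc["coef_length"]
        model.intercept_ = doc["intercept"]
        model.residual_scale_ = doc["residual_scale"]
        model.n_training_ = doc["n_training"]
        return model


def fit_rt_model(training: RTTrainingSet) -> RetentionTimeRegressor:
    """Least-squares (minimal-ridge) fit of RT on sequence composition."""
    if len(training) < MIN_TRAINING_PEPTIDES:
        raise InsufficientRTError(
            f"insufficient RT training data: {len(training)} unique peptides"
        )
    return RetentionTimeRegressor().fit(training.sequences, training.rts)


def rt_pvalue(
    model: RetentionTimeRegressor, peptide: str, observed_rt: float
) -> float:
    """Two-sided Gaussian tail probability of the studentised RT residual.

    p = erfc(|obs - pred| / (scale * sqrt(2))); identical observed and
    predicted RT gives p = 1, larger deviations give smaller p.  A zero
    residual scale degenerates to p = 1 at zero deviation and the floor
    1e-300 otherwise.
    """
    residual = observed_rt - model.predict_one(strip_modifications(peptide))
    if model.residual_scale_ == 0.0:
        return 1.0 if residual == 0.0 else P_FLOOR
    z = abs(residual) / model.residual_scale_
    p = float(special.erfc(z / np.sqrt(2.0)))
    return max(p, P_FLOOR)
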