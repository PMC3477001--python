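"""ROC analysis and discriminant-probability threshold selection.

After the discriminator assigns each PSM a probability P of being a
genuine (non-decoy) hit, the acceptance cutoff on P is swept: for a cutoff
theta, count the N PSMs with P > theta and the D decoys among them, and
estimate the FDR of the N - D accepted targets as D / (N - D).  The chosen
cutoff maximises the number of accepted targets subject to the estimate
staying at or below the user's bound epsilon.

The ROC curve (decoys as the negative class) is computed for diagnostics;
selection itself uses the decoy counts, because the decoy-based FPR and the
FDR of the accepted set are different quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .fdr import FDRCount, estimate_fdr
from .nn import ScoredPSM
from .psm import PSMRecord

__all__ = [
    "ROCCurve",
    "CalibrationResult",
    "compute_roc",
    "select_threshold",
    "pick_best_run",
]

#: sentinel cutoff accepting every record (all probabilities exceed it)
ACCEPT_ALL_THRESHOLD = -1.0


@dataclass(frozen=True)
class ROCCurve:
    """True-positive vs. false-positive rate over all probability cutoffs."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr, self.tpr))


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one threshold calibration on one scored stratum.

    ``accepted`` holds the target (non-decoy) PSMs with probability above
    the threshold; ``decoys_above`` the decoys above it, kept for pooled
    re-estimation when several runs are merged.  ``threshold`` is -1.0 when
    every record is accepted and 1.0 when nothing qualifies.
    """

    epsilon: float
    threshold: float
    accepted_scored: tuple[ScoredPSM, ...]
    decoys_above: tuple[ScoredPSM, ...]
    estimated_fdr: float
    run_index: Optional[int] = None

    @property
    def accepted(self) -> list[PSMRecord]:
        return [s.record for s in self.accepted_scored]

    @property
    def count(self) -> FDRCount:
        d = len(self.decoys_above)
        return FDRCount(d_t=d, n_t=d + len(self.accepted_scored))

    @property
    def n_accepted_targets(self) -> int:
        return len(self.accepted_scored)


def compute_roc(scored: Sequence[ScoredPSM]) -> ROCCurve:
    """ROC curve of the discriminant probabilities, decoys negative.

    One point per distinct probability value (ties grouped); AUC by the
    trapezoid rule.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    y = np.array([0 if s.record.is_decoy else 1 for s in scored])
    p = np.array([s.probability for s in scored])
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both decoy and target records")
    fpr, tpr, thr = _sk_roc_curve(y, p, drop_intermediate=False)
    return ROCCurve(tuple(fpr), tuple(tpr), tuple(thr), float(_sk_auc(fpr, tpr)))


def select_threshold(scored: Sequence[ScoredPSM], epsilon: float) -> CalibrationResult:
    """Choose the probability cutoff maximising accepted targets at FDR <= epsilon.

    Acceptance is strict (probability > cutoff).  Candidate cutoffs are the
    distinct probabilities plus a sentinel below all of them (accept
    everything); between two observed probabilities the accepted set is
    constant.  The FDR is not monotone in the cutoff, so the search is
    global rather than first-qualifying.  Ties break toward the smaller
    estimated FDR, then the higher cutoff.  If no cutoff qualifies, the
    result is empty with threshold 1.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    if not scored:
        return CalibrationResult(epsilon, 1.0, (), (), 0.0)

    probs = np.array([s.probability for s in scored])
    is_decoy = np.array([s.record.is_decoy for s in scored])
    order = np.argsort(-probs, kind="stable")
    p_sorted = probs[order]
    d_cum = np.cumsum(is_decoy[order])
    n_cum = np.arange(1, len(scored) + 1)

    # one candidate per distinct probability: cutting at value v accepts
    # exactly the records with probability > v, i.e. the prefix ending just
    # before the first occurrence of v in the sorted order
    distinct_last = np.nonzero(np.diff(p_sorted, append=-np.inf))[0]
    cand_thresholds = np.concatenate((p_sorted[distinct_last], [ACCEPT_ALL_THRESHOLD]))
    first_of_value = np.concatenate(([0], distinct_last[:-1] + 1))
    n_at = np.concatenate((first_of_value, [len(scored)], ))
    # n_at[i] records accepted at cand_thresholds[i]; pad cumsums with 0
    d_pad = np.concatenate(([0], d_cum))
    d_at = d_pad[n_at]
    t_at = n_at - d_at

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_at = np.where(
            t_at > 0, d_at / np.maximum(t_at, 1), np.where(d_at > 0, np.inf, 0.0)
        )
    feasible = fdr_at <= epsilon
    if not feasible.any():
        return CalibrationResult(epsilon, 1.0, (), (), 0.0)

    best_t = t_at[feasible].max()
    if best_t == 0:
        return CalibrationResult(epsilon, 1.0, (), (), 0.0)
    mask = feasible & (t_at == best_t)
    best_fdr = fdr_at[mask].min()
    mask &= fdr_at == best_fdr
    i = int(np.nonzero(mask)[0][np.argmax(cand_thresholds[mask])])

    theta = float(cand_thresholds[i])
    accepted = tuple(
        scored[k] for k in order[: n_at[i]] if not is_decoy[k]
    )
    decoys = tuple(scored[k] for k in order[: n_at[i]] if is_decoy[k])
    count = FDRCount(d_t=len(decoys), n_t=n_at[i])
    return CalibrationResult(
        epsilon=epsilon,
        threshold=theta,
        accepted_scored=accepted,
        decoys_above=decoys,
        estimated_fdr=estimate_fdr(count) if count.n_t else 0.0,
    )


def pick_best_run(results: Sequence[CalibrationResult]) -> CalibrationResult:
    """Most sensitive calibration among several runs.

    Maximises accepted targets; ties break toward the smaller estimated
    FDR, then the lowest run position in the input.
    """
    if not results:
        raise ValueError("pick_best_run requires at least one result")
    best = results[0]
    for r in results[1:]:
        if (r.n_accepted_targets, -r.estimated_fdr) > (
            best.n_accepted_targets,
            -best.estimated_fdr,
        ):
            best = r
    return best
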