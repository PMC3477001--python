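"""Decoy-based FDR estimation and exhaustive threshold search (BIDE).

With a composite target-decoy database, a wrong PSM is equally likely to
hit a target or a decoy sequence, so the decoy count D_T passing a set of
thresholds T estimates the number of wrong hits among the N_T - D_T target
PSMs passing the same thresholds.  The estimated false discovery rate of
the accepted target set is therefore

    FDR = D_T / (N_T - D_T)

``bide_search`` is the classical uni/bivariate decoy analysis: enumerate
every observed cutoff (or pair of cutoffs) and keep the combination that
maximises accepted targets while the estimate stays below a chosen bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .psm import FEATURE_NAMES, PSMRecord

__all__ = [
    "FDRCount",
    "FilterThresholds",
    "estimate_fdr",
    "apply_thresholds",
    "bide_search",
]

# Filtering direction per feature: "lower" keeps values >= bound,
# "upper" keeps values <= bound (absolute value for the mass deviation).
# Small RT p-values flag suspicious retention-time deviations, hence a
# lower bound.
_DIRECTIONS = {
    "xcorr": "lower",
    "delta_cn": "lower",
    "perc_ions": "lower",
    "delta_mass_ppm": "upper",
    "sp_rank": "upper",
    "rt_pvalue": "lower",
}


@dataclass(frozen=True)
class FDRCount:
    """Decoy (d_t) and total (n_t) PSM counts passing a threshold set."""

    d_t: int
    n_t: int

    def __post_init__(self) -> None:
        if not 0 <= self.d_t <= self.n_t:
            raise ValueError(f"need 0 <= d_t <= n_t, got d_t={self.d_t}, n_t={self.n_t}")

    @property
    def targets(self) -> int:
        """Accepted target (non-decoy) PSMs, n_t - d_t."""
        return self.n_t - self.d_t


@dataclass(frozen=True)
class FilterThresholds:
    """Per-feature score bounds; a ``None`` bound imposes no constraint.

    Lower bounds apply to xcorr, delta_cn, perc_ions and rt_pvalue;
    upper bounds apply to sp_rank and to the absolute mass deviation.
    """

    xcorr_min: Optional[float] = None
    delta_cn_min: Optional[float] = None
    perc_ions_min: Optional[float] = None
    abs_delta_mass_max: Optional[float] = None
    sp_rank_max: Optional[float] = None
    rt_pvalue_min: Optional[float] = None

    def __post_init__(self) -> None:
        for name, bound in self.__dict__.items():
            if bound is not None and not np.isfinite(bound):
                raise ValueError(f"bound {name} must be finite, got {bound}")

    def accepts(self, record: PSMRecord) -> bool:
        if self.xcorr_min is not None and record.xcorr < self.xcorr_min:
            return False
        if self.delta_cn_min is not None and record.delta_cn < self.delta_cn_min:
            return False
        if self.perc_ions_min is not None and record.perc_ions < self.perc_ions_min:
            return False
        if (
            self.abs_delta_mass_max is not None
            and abs(record.delta_mass_ppm) > self.abs_delta_mass_max
        ):
            return False
        if self.sp_rank_max is not None and record.sp_rank > self.sp_rank_max:
            return False
        if self.rt_pvalue_min is not None:
            if record.rt_pvalue is None or record.rt_pvalue < self.rt_pvalue_min:
                return False
        return True


def estimate_fdr(count: FDRCount) -> float:
    """Estimated FDR d_t / (n_t - d_t) of the accepted target set.

    An empty selection (n_t = 0) makes no false discoveries and returns 0.

    Raises
    ------
    ValueError
        If the selection contains only decoys (n_t = d_t > 0), where the
        estimate is undefined.
    """
    if count.n_t == 0:
        return 0.0
    if count.d_t == count.n_t:
        raise ValueError(
            f"undefined FDR: no target hits among {count.n_t} accepted PSMs"
        )
    return count.d_t / (count.n_t - count.d_t)


def apply_thresholds(
    records: Sequence[PSMRecord], thresholds: FilterThresholds
) -> tuple[list[PSMRecord], FDRCount]:
    """Filter records through a threshold set and count decoys among survivors."""
    accepted = [r for r in records if thresholds.accepts(r)]
    d_t = sum(r.is_decoy for r in accepted)
    return accepted, FDRCount(d_t=d_t, n_t=len(accepted))


def _goodness(records: Sequence[PSMRecord], feature: str) -> np.ndarray:
    """Map a feature to a scale where acceptance is value >= cutoff."""
    vals = np.array([r.feature(feature) for r in records], dtype=float)
    if feature == "delta_mass_ppm":
        return -np.abs(vals)
    if _DIRECTIONS[feature] == "upper":
        return -vals
    return vals


def _bound_from_cutoff(feature: str, cutoff: float) -> Optional[float]:
    """Invert _goodness: original-space bound for a transformed cutoff."""
    if not np.isfinite(cutoff):
        return None
    return -cutoff if _DIRECTIONS[feature] == "upper" else cutoff


_FIELD_OF = {
    "xcorr": "xcorr_min",
    "delta_cn": "delta_cn_min",
    "perc_ions": "perc_ions_min",
    "delta_mass_ppm": "abs_delta_mass_max",
    "sp_rank": "sp_rank_max",
    "rt_pvalue": "rt_pvalue_min",
}


def bide_search(
    records: Sequence[PSMRecord],
    features: Sequence[str],
    epsilon: float,
) -> tuple[Optional[FilterThresholds], list[PSMRecord]]:
    """Exhaustive decoy analysis over one or two score thresholds.

    Evaluates every combination of observed cutoffs (plus "no constraint")
    over the chosen features and returns the thresholds maximising the
    number of accepted target PSMs subject to ``estimate_fdr <= epsilon``.
    Ties break toward fewer accepted decoys, then toward the stricter
    cutoff on the first-listed feature.  Between two observed values the
    accepted set is constant, so restricting cutoffs to observed values
    loses no optima.

    Returns ``(None, [])`` when no cutoff combination satisfies the bound.
    """
    if not records:
        raise ValueError("bide_search requires a non-empty record collection")
    if not 1 <= len(features) <= 2:
        raise ValueError("bide_search explores one or two features")
    for f in features:
        if f not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {f!r}")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")

    is_decoy = np.array([r.is_decoy for r in records], dtype=bool)
    g = [_goodness(records, f) for f in features]
    # candidate cutoffs: observed values, ascending, plus -inf (no constraint)
    cand = [np.concatenate(([-np.inf], np.unique(gi))) for gi in g]

    if len(features) == 1:
        ranks = np.searchsorted(cand[0], g[0])  # index of each value's cutoff
        n1 = len(cand[0])
        tot = np.bincount(ranks, minlength=n1)
        dec = np.bincount(ranks[is_decoy], minlength=n1)
        # records at cutoff index i pass every cutoff index <= i
        n_t = np.cumsum(tot[::-1])[::-1]
        d_t = np.cumsum(dec[::-1])[::-1]
    else:
        ranks = [np.searchsorted(c, gi) for c, gi in zip(cand, g)]
        n1, n2 = len(cand[0]), len(cand[1])
        tot = np.zeros((n1, n2), dtype=np.int64)
        dec = np.zeros((n1, n2), dtype=np.int64)
        np.add.at(tot, (ranks[0], ranks[1]), 1)
        np.add.at(dec, (ranks[0][is_decoy], ranks[1][is_decoy]), 1)
        # suffix-sum both axes: counts passing (cutoff_i, cutoff_j)
        n_t = np.cumsum(np.cumsum(tot[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
        d_t = np.cumsum(np.cumsum(dec[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]

    targets = n_t - d_t
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(targets > 0, d_t / np.maximum(targets, 1), np.where(d_t > 0, np.inf, 0.0))
    feasible = fdr <= epsilon
    if not feasible.any():
        return None, []

    best_t = targets[feasible].max()
    mask = feasible & (targets == best_t)
    best_d = d_t[mask].min()
    mask &= d_t == best_d
    idx = np.argwhere(mask)
    # stricter = larger transformed cutoff = larger candidate index
    i = idx[np.lexsort((idx[:, -1] if idx.shape[1] > 1 else idx[:, 0], idx[:, 0]))][-1]

    kwargs = {
        _FIELD_OF[f]: _bound_from_cutoff(f, cand[k][i[k]]) for k, f in enumerate(features)
    }
    thresholds = FilterThresholds(**kwargs)
    accepted, count = apply_thresholds(records, thresholds)
    assert count.targets == best_t and count.d_t == best_d
    return thresholds, accepted
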