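"""Two-pass orchestration of the full PSM-assessment framework.

Per stratum (phospho-status x precursor charge, processed independently):

1. **First pass, epsilon = 0.**  The six-run discriminator protocol is
   trained on the five search-engine features (Xcorr, deltaCn, deltaM,
   SpRank, fraction of matched ions) and calibrated to accept zero decoys.
   The accepted, near-certain identifications supply (sequence, RT) pairs.
2. **RT model.**  A retention-time predictor is fitted on those pairs and
   every PSM in the stratum receives an RT p-value, the sixth feature.
3. **Second pass, user epsilon.**  The protocol runs again on all six
   features; the cutoff maximising accepted targets at estimated
   FDR <= epsilon is selected per run, and either the single most
   sensitive run is reported or the runs' acceptances are merged under a
   pooled-decoy re-estimate.

A stratum whose first pass yields fewer than 10 unique confident peptides
degrades to the five-feature path (skipping RT is a legitimate, faster
mode; it just loses discriminatory power).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .calibrate import CalibrationResult, pick_best_run, select_threshold
from .fdr import FDRCount, estimate_fdr
from .nn import PROTOCOL_RUNS, ScoredPSM, run_protocol
from .psm import FIVE_FEATURES, SIX_FEATURES, PSMRecord, Stratum, label_decoys, stratify
from .rt import (
    InsufficientRTError,
    RetentionTimeRegressor,
    build_rt_training_set,
    fit_rt_model,
    rt_pvalue,
)

__all__ = [
    "PipelineConfig",
    "StratumResult",
    "PipelineResult",
    "run_first_pass",
    "run_second_pass",
    "merge_accepted",
    "run_full",
]

#: seed offset between strata, so no two strata share run seeds
_STRATUM_SEED_STRIDE = 101


@dataclass(frozen=True)
class PipelineConfig:
    """User-facing knobs of a full run.

    epsilon defaults to 0.01, the FDR usually regarded as the best
    sensitivity/precision trade-off for PSM assessment.
    """

    epsilon: float = 0.01
    use_rt: bool = True
    base_seed: int = 0
    decoy_prefix: str = "REV_"
    merge_runs: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if not self.decoy_prefix:
            raise ValueError("decoy_prefix must be non-empty")


@dataclass(frozen=True)
class StratumResult:
    """Everything the pipeline decided for one stratum."""

    label: str
    phospho: bool
    charge: int
    n_records: int
    stratum_seed: int
    rt_used: bool
    results: tuple[CalibrationResult, ...]
    best: CalibrationResult
    merged_accepted: Optional[tuple[PSMRecord, ...]] = None
    merged_count: Optional[FDRCount] = None
    merged_fdr: Optional[float] = None
    rt_model: Optional[RetentionTimeRegressor] = None
    first_pass_accepted: Optional[int] = None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class PipelineResult:
    """Per-stratum outcomes plus drop tally and full provenance."""

    strata: tuple[StratumResult, ...]
    dropped: int
    config: PipelineConfig
    provenance: dict = field(default_factory=dict)

    @property
    def accepted(self) -> list[PSMRecord]:
        """All accepted target PSMs (merged sets where available)."""
        out: list[PSMRecord] = []
        for s in self.strata:
            out.extend(s.merged_accepted if s.merged_accepted is not None else s.best.accepted)
        return out

    @property
    def warnings(self) -> list[str]:
        return [w for s in self.strata for w in s.warnings]


def _calibrated_protocol(
    records: Sequence[PSMRecord],
    feature_list: Sequence[str],
    epsilon: float,
    base_seed: int,
) -> tuple[CalibrationResult, ...]:
    scored_runs = run_protocol(records, feature_list, base_seed)
    return tuple(
        replace(select_threshold(scored, epsilon), run_index=i)
        for i, scored in enumerate(scored_runs, start=1)
    )


def run_first_pass(stratum: Stratum, base_seed: int) -> list[PSMRecord]:
    """Best epsilon = 0 acceptance over the six runs on five features."""
    results = _calibrated_protocol(stratum.records, FIVE_FEATURES, 0.0, base_seed)
    return pick_best_run(results).accepted


def run_second_pass(
    stratum: Stratum,
    epsilon: float,
    base_seed: int,
    feature_list: Sequence[str] = SIX_FEATURES,
) -> tuple[CalibrationResult, ...]:
    """Six calibrated runs at the user's epsilon (six features by default)."""
    return _calibrated_protocol(stratum.records, feature_list, epsilon, base_seed)


def merge_accepted(
    results: Sequence[CalibrationResult], epsilon: float
) -> tuple[list[PSMRecord], FDRCount, float]:
    """Union the runs' acceptances and re-control the FDR on the pool.

    Targets accepted by any run and decoys above any run's threshold are
    pooled by spectrum_id, each keeping its maximum per-run probability.
    The pooled FDR is re-estimated from the pooled decoy count; while it
    exceeds epsilon, the pooled record (target or decoy) with the lowest
    maximum probability is removed — dropping low-probability decoys is
    what brings the estimate back under the bound.  Deterministic; ties
    in probability remove the lexicographically smaller spectrum_id first.
    """
    pool: dict[str, ScoredPSM] = {}
    for res in results:
        for s in list(res.accepted_scored) + list(res.decoys_above):
            sid = s.record.spectrum_id
            if sid not in pool or s.probability > pool[sid].probability:
                pool[sid] = s
    items = sorted(pool.values(), key=lambda s: (s.probability, s.record.spectrum_id))
    if not items:
        return [], FDRCount(0, 0), 0.0

    decoy = np.array([s.record.is_decoy for s in items])
    n_total = len(items)
    d_total = int(decoy.sum())
    removed_d = np.concatenate(([0], np.cumsum(decoy)))  # after k removals
    for k in range(n_total + 1):
        d = d_total - removed_d[k]
        n = n_total - k
        t = n - d
        if t > 0:
            if d / t <= epsilon:
                break
        elif d == 0:
            break
    keep = items[k:]
    accepted = [s.record for s in reversed(keep) if not s.record.is_decoy]
    d = sum(s.record.is_decoy for s in keep)
    count = FDRCount(d_t=d, n_t=len(keep))
    return accepted, count, estimate_fdr(count) if count.n_t else 0.0


def run_full(records: Sequence[PSMRecord], config: PipelineConfig) -> PipelineResult:
    """Label decoys, stratify, and run the two-pass framework per stratum."""
    labeled = label_decoys(records, config.decoy_prefix)
    strata, dropped = stratify(labeled)

    out: list[StratumResult] = []
    for idx, stratum in enumerate(strata):
        seed = (config.base_seed + _STRATUM_SEED_STRIDE * idx) % (2**31)
        warnings: list[str] = []
        rt_model: Optional[RetentionTimeRegressor] = None
        first_n: Optional[int] = None
        features = FIVE_FEATURES
        working = stratum
        rt_used = False

        if config.use_rt:
            try:
                confident = run_first_pass(stratum, seed)
                first_n = len(confident)
                rt_model = fit_rt_model(build_rt_training_set(confident))
                working = Stratum(
                    phospho=stratum.phospho,
                    charge=stratum.charge,
                    records=tuple(
                        replace(r, rt_pvalue=rt_pvalue(rt_model, r.peptide, r.rt_observed_s))
                        for r in stratum.records
                    ),
                )
                features = SIX_FEATURES
                rt_used = True
            except InsufficientRTError as exc:
                warnings.append(
                    f"stratum {stratum.label}: {exc}; degraded to five-feature mode"
                )
                rt_model = None

        results = run_second_pass(working, config.epsilon, seed, features)
        best = pick_best_run(results)
        if best.n_accepted_targets < 10:
            warnings.append(
                f"stratum {stratum.label}: only {best.n_accepted_targets} accepted "
                "PSMs (fewer than 10 correct assignments)"
            )

        merged = merged_count = merged_fdr = None
        if config.merge_runs:
            acc, cnt, mfdr = merge_accepted(results, config.epsilon)
            merged, merged_count, merged_fdr = tuple(acc), cnt, mfdr

        out.append(
            StratumResult(
                label=stratum.label,
                phospho=stratum.phospho,
                charge=stratum.charge,
                n_records=len(stratum),
                stratum_seed=seed,
                rt_used=rt_used,
                results=results,
                best=best,
                merged_accepted=merged,
                merged_count=merged_count,
                merged_fdr=merged_fdr,
                rt_model=rt_model,
                first_pass_accepted=first_n,
                warnings=tuple(warnings),
            )
        )

    provenance = {
        "version": __version__,
        "config": {
            "epsilon": config.epsilon,
            "use_rt": config.use_rt,
            "base_seed": config.base_seed,
            "decoy_prefix": config.decoy_prefix,
            "merge_runs": config.merge_runs,
        },
        "protocol_runs": [
            {"run": i, "n_hidden": h, "learning_rate": lr, "epochs": ep, "momentum": 0.2}
            for i, (h, lr, ep) in enumerate(PROTOCOL_RUNS, start=1)
        ],
        "stratum_seeds": {
            s.label: s.stratum_seed for s in out
        },
    }
    return PipelineResult(
        strata=tuple(out), dropped=dropped, config=config, provenance=provenance
    )
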