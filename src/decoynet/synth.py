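"""Synthetic PSM generator with ground-truth correctness labels.

The generator realises the statistical structure that target-decoy
analysis assumes: a PSM population that is a three-part mixture of

* correct target hits, drawn from a "good-score" component,
* incorrect target hits, and
* decoy hits, drawn i.i.d. from the *same* "bad-score" component as the
  incorrect targets — a wrong match is equally likely to land on a target
  or a decoy sequence, which is exactly what makes the decoy count an
  estimate of the number of wrong target hits.

Class-conditional features are multivariate Gaussian on a latent scale
(xcorr, deltaCn, fraction of matched ions, mass deviation in ppm, and
log SpRank) and then clipped/rounded into their legal ranges.  Retention
times of correct hits follow a linear amino-acid-composition model plus
Gaussian noise; wrong hits elute uniformly over the run.  Phosphopeptide
strata shift the correct component's score means downward (phosphopeptide
spectra score systematically lower).  Ground-truth labels are returned
separately and are never written into a PSM table.

Default magnitudes are chosen to mimic a typical phosphoproteomics search:
under 20% of target PSMs are correct, each feature carries moderate signal,
and no single feature separates the classes on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .psm import PSMRecord
from .rt import AMINO_ACIDS

__all__ = ["GeneratorConfig", "generate_stratum", "generate_dataset"]

#: latent feature order of the mean/covariance parameters
LATENT_FEATURES = ("xcorr", "delta_cn", "perc_ions", "delta_mass_ppm", "log_sp_rank")

# per-residue retention contribution in seconds, reversed-phase-like:
# aromatic/aliphatic residues retained longest, charged residues least
_HYDRO = {
    "W": 32.7, "F": 27.8, "L": 23.7, "I": 21.5, "M": 14.8, "V": 13.2,
    "Y": 12.0, "C": 8.0, "A": 4.2, "P": 5.5, "T": 3.0, "E": 2.5,
    "D": 1.5, "S": 0.5, "Q": 0.2, "G": 0.0, "N": -0.5, "R": -2.5,
    "H": -4.5, "K": -5.0,
}
DEFAULT_RT_COEFFICIENTS = tuple(8.0 * _HYDRO[a] for a in AMINO_ACIDS)
DEFAULT_RT_LENGTH_COEF = 12.0
DEFAULT_RT_INTERCEPT = 400.0


def _block_cov(sds: Sequence[float], rho: float = 0.3) -> tuple[tuple[float, ...], ...]:
    """Covariance with correlation rho among the three ion-quality scores."""
    sds = np.asarray(sds, dtype=float)
    corr = np.eye(5)
    for i in (0, 1, 2):
        for j in (0, 1, 2):
            if i != j:
                corr[i, j] = rho
    cov = corr * np.outer(sds, sds)
    return tuple(map(tuple, cov))


@dataclass(frozen=True)
class GeneratorConfig:
    """Distributional parameters of the synthetic PSM mixture.

    ``correct_fraction`` is the fraction of *target* PSMs that are correct;
    ``decoy_fraction`` the share of all rows that are decoys (fixed count
    ``round(n * decoy_fraction)`` per stratum for reproducible arithmetic).
    ``phospho_score_shift`` lowers the correct component's xcorr/deltaCn/
    perc_ions means by that many component standard deviations in phospho
    strata.  ``rt_signal = False`` removes the composition-RT relationship
    (all rows elute uniformly), for experiments on the value of the RT
    feature.
    """

    n_per_stratum: int = 1000
    correct_fraction: float = 0.18
    decoy_fraction: float = 0.45
    correct_mean: tuple[float, ...] = (3.1, 0.28, 0.50, 0.0, 0.9)
    correct_cov: tuple[tuple[float, ...], ...] = field(
        default_factory=lambda: _block_cov((0.7, 0.10, 0.12, 1.5, 0.8))
    )
    incorrect_mean: tuple[float, ...] = (1.8, 0.06, 0.25, 0.0, 2.7)
    incorrect_cov: tuple[tuple[float, ...], ...] = field(
        default_factory=lambda: _block_cov((0.5, 0.05, 0.08, 4.0, 1.0))
    )
    phospho_score_shift: float = -0.5
    rt_coefficients: tuple[float, ...] = DEFAULT_RT_COEFFICIENTS
    rt_length_coef: float = DEFAULT_RT_LENGTH_COEF
    rt_intercept: float = DEFAULT_RT_INTERCEPT
    rt_noise_sd: float = 60.0
    run_length_s: float = 3600.0
    rt_signal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_stratum < 1:
            raise ValueError("n_per_stratum must be >= 1")
        if not 0.0 <= self.correct_fraction <= 1.0:
            raise ValueError("correct_fraction must lie in [0, 1]")
        if not 0.0 < self.decoy_fraction < 1.0:
            raise ValueError("decoy_fraction must lie in (0, 1)")
        if self.phospho_score_shift > 0:
            raise ValueError("phospho_score_shift must be non-positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("correct_cov", "incorrect_cov"):
            cov = np.asarray(getattr(self, name), dtype=float)
            if cov.shape != (5, 5) or not np.allclose(cov, cov.T):
                raise ValueError(f"{name} must be a symmetric 5x5 matrix")
            if np.linalg.eigvalsh(cov).min() < -1e-9:
                raise ValueError(f"{name} is not positive semi-definite")


def _random_peptide(rng: np.random.Generator, phospho: bool) -> str:
    """Tryptic-like peptide: 7-25 residues ending in K/R; >= 1 S/T/Y[p] if phospho."""
    length = int(rng.integers(7, 26))
    residues = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length - 1)]
    residues.append("K" if rng.random() < 0.5 else "R")
    if phospho:
        pos = int(rng.integers(0, length - 1))
        residues[pos] = "STY"[int(rng.integers(0, 3))] + "[p]"
    return "".join(residues)


def _predict_rt(config: GeneratorConfig, sequence: str) -> float:
    coef = dict(zip(AMINO_ACIDS, config.rt_coefficients))
    return (
        config.rt_intercept
        + config.rt_length_coef * len(sequence)
        + sum(coef[a] for a in sequence)
    )


def generate_stratum(
    config: GeneratorConfig, phospho: bool, charge: int
) -> tuple[list[PSMRecord], np.ndarray]:
    """Generate one phospho x charge stratum with ground-truth labels.

    Returns ``(records, is_correct)`` where ``is_correct[i]`` is True for
    correct target hits (decoys and incorrect targets are False).  Row
    order is shuffled so classes are interleaved; deterministic under
    (config.seed, phospho, charge).
    """
    if charge not in (2, 3):
        raise ValueError("charge must be 2 or 3")
    rng = np.random.default_rng([config.seed, int(phospho), charge])

    n = config.n_per_stratum
    n_decoy = round(n * config.decoy_fraction)
    n_target = n - n_decoy
    n_correct = round(n_target * config.correct_fraction)
    n_wrong = n_decoy + (n_target - n_correct)

    correct_mean = np.asarray(config.correct_mean, dtype=float)
    if phospho:
        sds = np.sqrt(np.diag(np.asarray(config.correct_cov)))
        shift = np.zeros(5)
        shift[:3] = config.phospho_score_shift * sds[:3]
        correct_mean = correct_mean + shift

    latents = np.empty((n, 5))
    # wrong rows (decoys + incorrect targets) are i.i.d. from one component
    latents[:n_wrong] = rng.multivariate_normal(
        config.incorrect_mean, np.asarray(config.incorrect_cov), size=n_wrong
    )
    if n_correct:
        latents[n_wrong:] = rng.multivariate_normal(
            correct_mean, np.asarray(config.correct_cov), size=n_correct
        )

    is_decoy = np.zeros(n, dtype=bool)
    is_decoy[:n_decoy] = True  # first n_decoy of the wrong block are decoys
    is_correct = np.zeros(n, dtype=bool)
    is_correct[n_wrong:] = True

    xcorr = np.clip(latents[:, 0], 0.0, None)
    delta_cn = np.clip(latents[:, 1], 0.0, 1.0)
    perc_ions = np.clip(latents[:, 2], 0.0, 1.0)
    delta_mass = latents[:, 3]
    sp_rank = np.maximum(1, np.rint(np.exp(latents[:, 4]))).astype(int)

    peptides = [_random_peptide(rng, phospho) for _ in range(n)]
    rt = rng.uniform(0.0, config.run_length_s, size=n)
    if config.rt_signal:
        from .rt import strip_modifications

        for i in np.nonzero(is_correct)[0]:
            rt[i] = _predict_rt(config, strip_modifications(peptides[i]))
            rt[i] += rng.normal(0.0, config.rt_noise_sd)
    rt = np.clip(rt, 0.0, config.run_length_s)

    label = f"{'PH' if phospho else 'NPH'}_CH{charge}"
    order = rng.permutation(n)
    records: list[PSMRecord] = []
    for pos, i in enumerate(order):
        acc = f"{'REV_' if is_decoy[i] else ''}IPI{rng.integers(0, 10**8):08d}"
        records.append(
            PSMRecord(
                spectrum_id=f"{label}_scan{pos:06d}",
                peptide=peptides[i],
                protein=acc,
                charge=charge,
                xcorr=float(xcorr[i]),
                delta_cn=float(delta_cn[i]),
                delta_mass_ppm=float(delta_mass[i]),
                sp_rank=int(sp_rank[i]),
                perc_ions=float(perc_ions[i]),
                rt_observed_s=float(rt[i]),
                rt_pvalue=None,
                is_decoy=bool(is_decoy[i]),
                is_phospho=phospho,
            )
        )
    return records, is_correct[order]


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[PSMRecord], dict[str, bool]]:
    """Generate all four strata ({non-phospho, phospho} x {+2, +3}).

    Returns the concatenated records (distinct spectrum_ids across strata)
    and a ground-truth map spectrum_id -> is_correct.
    """
    records: list[PSMRecord] = []
    truth: dict[str, bool] = {}
    for phospho in (False, True):
        for charge in (2, 3):
            recs, correct = generate_stratum(config, phospho, charge)
            records.extend(recs)
            truth.update(
                {r.spectrum_id: bool(c) for r, c in zip(recs, correct)}
            )
    return records, truth
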