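"""Peptide-spectrum-match records, canonical table I/O and stratification.

A PSM (peptide-spectrum match) is the assignment of a peptide sequence to
one MS/MS spectrum by a database-search engine such as SEQUEST.  Each record
carries the six quality features used by the multivariate target-decoy
analysis (Xcorr, deltaCn, deltaM in ppm, SpRank, fraction of matched ions,
and a retention-time p-value), a precursor charge, and two derived flags:
whether the best-hit protein is a decoy and whether the assigned peptide is
a phosphopeptide.

The canonical on-disk format is a UTF-8, tab-separated table with one header
row.  The decoy and phospho flags are derived from the protein accession and
the peptide modification annotations, respectively; they are never stored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "PSMRecord",
    "Stratum",
    "COLUMNS",
    "FEATURE_NAMES",
    "FIVE_FEATURES",
    "SIX_FEATURES",
    "read_psm_table",
    "write_psm_table",
    "label_decoys",
    "stratify",
]

#: Canonical column order of the tab-separated PSM table.
COLUMNS = (
    "spectrum_id",
    "peptide",
    "protein",
    "charge",
    "xcorr",
    "delta_cn",
    "delta_mass_ppm",
    "sp_rank",
    "perc_ions",
    "rt_observed_s",
    "rt_pvalue",
)

#: The six quality features, in canonical order.
FEATURE_NAMES = (
    "xcorr",
    "delta_cn",
    "delta_mass_ppm",
    "sp_rank",
    "perc_ions",
    "rt_pvalue",
)

#: The five search-engine features used before retention time is available.
FIVE_FEATURES = FEATURE_NAMES[:5]
#: All six features, including the RT p-value.
SIX_FEATURES = FEATURE_NAMES

_NUMERIC = {
    "charge": int,
    "xcorr": float,
    "delta_cn": float,
    "delta_mass_ppm": float,
    "sp_rank": int,
    "perc_ions": float,
    "rt_observed_s": float,
}

# phosphorylated residue annotation in the canonical dialect: S[p], T[p], Y[p]
_PHOSPHO_RE = re.compile(r"[STY]\[p\]")


@dataclass(frozen=True)
class PSMRecord:
    """One best-ranked peptide-spectrum match.

    Parameters
    ----------
    spectrum_id : str
        Opaque identifier of the MS/MS spectrum.
    peptide : str
        Assigned peptide with inline modification annotations
        (e.g. ``"ALS[p]PTK"`` for phosphoserine).
    protein : str
        Accession of the single reported best-hit protein.
    charge : int
        Precursor charge state (>= 1).
    xcorr : float
        SEQUEST cross-correlation score (>= 0).
    delta_cn : float
        Normalised score gap to the runner-up candidate, in [0, 1].
    delta_mass_ppm : float
        Signed precursor mass deviation in parts per million.
    sp_rank : int
        Rank in the preliminary score (>= 1, lower is better).
    perc_ions : float
        Fraction of theoretical fragment ions matched, in [0, 1].
    rt_observed_s : float
        Observed chromatographic retention time in seconds (>= 0).
    rt_pvalue : float or None
        Probability-scaled retention-time deviation in (0, 1], or None
        before the RT model has been applied.
    is_decoy : bool
        True when the best-hit protein comes from the decoy database.
    is_phospho : bool
        True when the peptide carries at least one phosphorylation.
    """

    spectrum_id: str
    peptide: str
    protein: str
    charge: int
    xcorr: float
    delta_cn: float
    delta_mass_ppm: float
    sp_rank: int
    perc_ions: float
    rt_observed_s: float
    rt_pvalue: Optional[float] = None
    is_decoy: bool = False
    is_phospho: bool = False

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.sp_rank < 1:
            raise ValueError(f"sp_rank must be >= 1, got {self.sp_rank}")
        if not 0.0 <= self.delta_cn <= 1.0:
            raise ValueError(f"delta_cn must lie in [0, 1], got {self.delta_cn}")
        if not 0.0 <= self.perc_ions <= 1.0:
            raise ValueError(f"perc_ions must lie in [0, 1], got {self.perc_ions}")
        if self.rt_pvalue is not None and not 0.0 < self.rt_pvalue <= 1.0:
            raise ValueError(f"rt_pvalue must lie in (0, 1], got {self.rt_pvalue}")

    def feature(self, name: str) -> float:
        """Return one of the six quality features by canonical name."""
        if name not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {name!r}; expected one of {FEATURE_NAMES}")
        value = getattr(self, name)
        if value is None:
            raise ValueError(
                f"feature {name!r} absent in record {self.spectrum_id!r}"
            )
        return float(value)


@dataclass(frozen=True)
class Stratum:
    """A homogeneous subset of PSMs: one phospho-status x charge cell.

    Score distributions differ markedly between phosphopeptide and
    non-phosphopeptide spectra and between +2 and +3 precursors, so each
    stratum is modelled and calibrated independently.
    """

    phospho: bool
    charge: int
    records: tuple[PSMRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a stratum must contain at least one record")
        for r in self.records:
            if r.charge != self.charge or r.is_phospho != self.phospho:
                raise ValueError(
                    f"record {r.spectrum_id!r} (charge={r.charge}, "
                    f"phospho={r.is_phospho}) does not belong to stratum "
                    f"(charge={self.charge}, phospho={self.phospho})"
                )

    @property
    def label(self) -> str:
        return f"{'PH' if self.phospho else 'NPH'}_CH{self.charge}"

    def __len__(self) -> int:
        return len(self.records)


def is_phosphopeptide(peptide: str) -> bool:
    """True when the peptide string carries >= 1 phosphorylation annotation."""
    return _PHOSPHO_RE.search(peptide) is not None


def read_psm_table(path: str | Path) -> list[PSMRecord]:
    """Read the canonical tab-separated PSM table.

    Missing ``rt_pvalue`` cells become ``None``; row order is preserved.
    The phospho flag is derived from the peptide string; the decoy flag is
    left False (apply :func:`label_decoys` afterwards).

    Raises
    ------
    ValueError
        If a mandatory column is missing or a numeric cell cannot be parsed
        (the error names the offending row and column).
    FileNotFoundError
        If *path* does not exist.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} is missing mandatory column(s): {missing}")

    records: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = dict(zip(df.columns, row))
        kwargs: dict = {
            "spectrum_id": values["spectrum_id"],
            "peptide": values["peptide"],
            "protein": values["protein"],
        }
        for col, caster in _NUMERIC.items():
            cell = values[col]
            try:
                kwargs[col] = caster(float(cell)) if caster is int else caster(cell)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"unparseable value {cell!r} in column {col!r}, data row {i}"
                ) from exc
        pcell = values["rt_pvalue"].strip()
        if pcell == "":
            kwargs["rt_pvalue"] = None
        else:
            try:
                kwargs["rt_pvalue"] = float(pcell)
            except ValueError as exc:
                raise ValueError(
                    f"unparseable value {pcell!r} in column 'rt_pvalue', data row {i}"
                ) from exc
        kwargs["is_phospho"] = is_phosphopeptide(kwargs["peptide"])
        records.append(PSMRecord(**kwargs))
    return records


def write_psm_table(records: Iterable[PSMRecord], path: str | Path) -> None:
    """Write records to the canonical tab-separated format.

    Floats are written with enough digits (repr) that a read-back
    reproduces them exactly; absent ``rt_pvalue`` becomes an empty cell.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "spectrum_id": r.spectrum_id,
                "peptide": r.peptide,
                "protein": r.protein,
                "charge": r.charge,
                "xcorr": repr(r.xcorr),
                "delta_cn": repr(r.delta_cn),
                "delta_mass_ppm": repr(r.delta_mass_ppm),
                "sp_rank": r.sp_rank,
                "perc_ions": repr(r.perc_ions),
                "rt_observed_s": repr(r.rt_observed_s),
                "rt_pvalue": "" if r.rt_pvalue is None else repr(r.rt_pvalue),
            }
        )
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def label_decoys(
    records: Iterable[PSMRecord], decoy_prefix: str = "REV_"
) -> list[PSMRecord]:
    """Flag records whose protein accession starts with *decoy_prefix*.

    The composite search database appends reversed (decoy) protein
    sequences to the targets; hits to reversed entries are certainly wrong
    and calibrate the error rate among target hits.  Idempotent.
    """
    if not decoy_prefix:
        raise ValueError("decoy_prefix must be non-empty")
    return [
        replace(r, is_decoy=r.protein.startswith(decoy_prefix)) for r in records
    ]


def stratify(records: Sequence[PSMRecord]) -> tuple[list[Stratum], int]:
    """Split records into phospho-status x charge strata.

    Only precursor charges +2 and +3 are retained; other charges are
    dropped and counted.  Returns ``(strata, n_dropped)`` where the union
    of the strata plus the dropped records equals the input.

    Raises
    ------
    ValueError
        If every record is dropped ("no usable strata").
    """
    buckets: dict[tuple[bool, int], list[PSMRecord]] = {}
    dropped = 0
    for r in records:
        if r.charge not in (2, 3):
            dropped += 1
            continue
        buckets.setdefault((r.is_phospho, r.charge), []).append(r)
    if not buckets:
        raise ValueError("no usable strata: all records dropped or input empty")
    strata = [
        Stratum(phospho=ph, charge=ch, records=tuple(buckets[(ph, ch)]))
        for ph in (False, True)
        for ch in (2, 3)
        if (ph, ch) in buckets
    ]
    return strata, dropped
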