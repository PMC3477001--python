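"""Small built-in example data.

``worked_example_psms`` is a synthetic reconstruction of the classic
twelve-PSM illustration of why multivariate decoy filtering beats a single
score: with these Xcorr / deltaCn values, filtering on Xcorr alone at an
estimated FDR of 0 retrieves exactly three target hits (every lower Xcorr
cutoff admits the top decoy), while adding a deltaCn threshold retrieves
five (the two extra targets have middling Xcorr but a clear runner-up gap,
where the decoys combine decent Xcorr with a poor gap or vice versa).
"""

from __future__ import annotations

from .psm import PSMRecord

__all__ = ["worked_example_psms"]

# (spectrum, xcorr, delta_cn, decoy?)
_EXAMPLE_ROWS = (
    ("scan0001", 4.12, 0.30, False),
    ("scan0002", 3.92, 0.25, False),
    ("scan0003", 3.64, 0.28, False),
    ("scan0004", 3.41, 0.05, True),
    ("scan0005", 3.22, 0.35, False),
    ("scan0006", 3.05, 0.40, False),
    ("scan0007", 2.84, 0.32, True),
    ("scan0008", 2.61, 0.10, False),
    ("scan0009", 2.48, 0.15, True),
    ("scan0010", 2.21, 0.20, True),
    ("scan0011", 2.02, 0.12, False),
    ("scan0012", 1.83, 0.08, False),
)


def worked_example_psms() -> list[PSMRecord]:
    """Twelve synthetic PSMs illustrating uni- vs. bivariate decoy filtering.

    Eight target and four decoy charge-2 PSMs.  Fields other than Xcorr and
    deltaCn are plausible fillers and play no role in the example.
    """
    records = []
    for i, (sid, xcorr, dcn, decoy) in enumerate(_EXAMPLE_ROWS):
        records.append(
            PSMRecord(
                spectrum_id=sid,
                peptide="SAMPLEPEPTIDK",
                protein=("REV_IPI00000" if decoy else "IPI00000") + f"{i:03d}",
                charge=2,
                xcorr=xcorr,
                delta_cn=dcn,
                delta_mass_ppm=round(((-1) ** i) * 0.4 * (i + 1), 2),
                sp_rank=1 + (i % 4),
                perc_ions=round(0.30 + 0.02 * i, 2),
                rt_observed_s=600.0 + 90.0 * i,
                rt_pvalue=None,
                is_decoy=decoy,
                is_phospho=False,
            )
        )
    return records
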