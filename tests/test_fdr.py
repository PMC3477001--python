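"""FDR arithmetic, threshold filtering and the exhaustive BIDE search."""

import itertools

import numpy as np
import pytest

from decoynet.datasets import worked_example_psms
from decoynet.fdr import (
    FDRCount,
    FilterThresholds,
    apply_thresholds,
    bide_search,
    estimate_fdr,
)

from conftest import make_record


class TestEstimateFdr:
    def test_zero_numerator(self):
        assert estimate_fdr(FDRCount(0, 50)) == 0.0

    def test_basic_arithmetic(self):
        assert estimate_fdr(FDRCount(5, 105)) == 0.05

    def test_empty_selection_is_zero(self):
        assert estimate_fdr(FDRCount(0, 0)) == 0.0

    def test_all_decoy_selection_is_undefined(self):
        with pytest.raises(ValueError, match="no target hits"):
            estimate_fdr(FDRCount(3, 3))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            FDRCount(5, 3)

    def test_agrees_with_direct_recomputation_exhaustively(self):
        for n in range(0, 201):
            for d in range(0, n):
                assert estimate_fdr(FDRCount(d, n)) == d / (n - d)


def _brute_force_filter(records, t: FilterThresholds):
    """Independent per-record re-check of every bound."""
    out = []
    for r in records:
        ok = True
        if t.xcorr_min is not None:
            ok &= r.xcorr >= t.xcorr_min
        if t.delta_cn_min is not None:
            ok &= r.delta_cn >= t.delta_cn_min
        if t.perc_ions_min is not None:
            ok &= r.perc_ions >= t.perc_ions_min
        if t.abs_delta_mass_max is not None:
            ok &= abs(r.delta_mass_ppm) <= t.abs_delta_mass_max
        if t.sp_rank_max is not None:
            ok &= r.sp_rank <= t.sp_rank_max
        if t.rt_pvalue_min is not None:
            ok &= r.rt_pvalue is not None and r.rt_pvalue >= t.rt_pvalue_min
        if ok:
            out.append(r)
    return out


class TestApplyThresholds:
    def test_empty_thresholds_accept_everything(self, small_stratum):
        records, _ = small_stratum
        accepted, count = apply_thresholds(records, FilterThresholds())
        assert len(accepted) == len(records) == count.n_t

    def test_unreachable_bound_accepts_nothing(self, small_stratum):
        records, _ = small_stratum
        hi = max(r.xcorr for r in records) + 1
        accepted, count = apply_thresholds(records, FilterThresholds(xcorr_min=hi))
        assert accepted == [] and count == FDRCount(0, 0)

    def test_random_thresholds_match_brute_force(self, small_stratum, rng):
        records, _ = small_stratum
        for _ in range(50):
            t = FilterThresholds(
                xcorr_min=float(rng.uniform(0, 4)) if rng.random() < 0.7 else None,
                delta_cn_min=float(rng.uniform(0, 0.4)) if rng.random() < 0.7 else None,
                perc_ions_min=float(rng.uniform(0, 0.6)) if rng.random() < 0.5 else None,
                abs_delta_mass_max=float(rng.uniform(1, 10)) if rng.random() < 0.5 else None,
                sp_rank_max=float(rng.integers(1, 40)) if rng.random() < 0.5 else None,
            )
            accepted, count = apply_thresholds(records, t)
            oracle = _brute_force_filter(records, t)
            assert accepted == oracle
            assert count.d_t == sum(r.is_decoy for r in oracle)

    def test_strengthening_a_bound_never_grows_counts(self, small_stratum):
        records, _ = small_stratum
        _, loose = apply_thresholds(records, FilterThresholds(xcorr_min=1.5))
        _, tight = apply_thresholds(records, FilterThresholds(xcorr_min=2.5))
        assert tight.n_t <= loose.n_t and tight.d_t <= loose.d_t
        _, loose = apply_thresholds(records, FilterThresholds(sp_rank_max=20))
        _, tight = apply_thresholds(records, FilterThresholds(sp_rank_max=5))
        assert tight.n_t <= loose.n_t and tight.d_t <= loose.d_t


def _brute_force_bide(records, features, epsilon):
    """Enumerate every cutoff combination; return the best target count."""
    cand = {}
    for f in features:
        vals = sorted({r.feature(f) for r in records})
        if f == "delta_mass_ppm":
            cand[f] = sorted({abs(v) for v in vals}) + [np.inf]
        elif f in ("sp_rank",):
            cand[f] = vals + [np.inf]
        else:
            cand[f] = [-np.inf] + vals
    best = 0  # the empty acceptance is always feasible
    for combo in itertools.product(*(cand[f] for f in features)):
        acc = []
        for r in records:
            ok = True
            for f, c in zip(features, combo):
                v = r.feature(f)
                if f == "delta_mass_ppm":
                    ok &= abs(v) <= c
                elif f == "sp_rank":
                    ok &= v <= c
                else:
                    ok &= v >= c
            if ok:
                acc.append(r)
        d = sum(r.is_decoy for r in acc)
        t = len(acc) - d
        if (t > 0 and d / t <= epsilon) or (t == 0 and d == 0):
            best = max(best, t)
    return best


class TestBideSearch:
    def test_worked_example_xcorr_only(self):
        _, accepted = bide_search(worked_example_psms(), ("xcorr",), 0.0)
        assert sum(not r.is_decoy for r in accepted) == 3
        assert sum(r.is_decoy for r in accepted) == 0

    def test_worked_example_xcorr_plus_delta_cn(self):
        _, accepted = bide_search(
            worked_example_psms(), ("xcorr", "delta_cn"), 0.0
        )
        assert sum(not r.is_decoy for r in accepted) == 5
        assert sum(r.is_decoy for r in accepted) == 0

    def test_no_decoys_accepts_everything_at_zero(self):
        records = [make_record(i) for i in range(8)]
        thresholds, accepted = bide_search(records, ("xcorr",), 0.0)
        assert len(accepted) == 8

    def test_infeasible_bound_returns_empty_without_error(self):
        # the single best-scoring record is a decoy dominating every cut
        records = [
            make_record(0, protein="REV_X", is_decoy=True, xcorr=9.9, delta_cn=0.9),
            make_record(1, xcorr=1.0, delta_cn=0.9),
        ]
        thresholds, accepted = bide_search(records, ("delta_cn",), 0.0)
        assert thresholds is None and accepted == []

    @pytest.mark.parametrize("features", [("xcorr",), ("xcorr", "delta_cn"),
                                          ("sp_rank", "delta_mass_ppm")])
    @pytest.mark.parametrize("epsilon", [0.0, 0.05, 0.2])
    def test_matches_brute_force_on_small_inputs(self, features, epsilon, rng):
        for trial in range(8):
            n = int(rng.integers(5, 31))
            records = [
                make_record(
                    i,
                    protein="REV_X" if rng.random() < 0.4 else "X",
                    is_decoy=False,
                    xcorr=float(rng.uniform(0, 5)),
                    delta_cn=float(rng.uniform(0, 0.5)),
                    delta_mass_ppm=float(rng.normal(0, 4)),
                    sp_rank=int(rng.integers(1, 20)),
                )
                for i in range(n)
            ]
            from decoynet.psm import label_decoys

            records = label_decoys(records)
            _, accepted = bide_search(records, features, epsilon)
            got = sum(not r.is_decoy for r in accepted)
            assert got == _brute_force_bide(records, features, epsilon)

    def test_second_feature_never_hurts(self, rng):
        """A bivariate search can always replicate the univariate optimum."""
        from decoynet.psm import label_decoys

        for trial in range(10):
            records = label_decoys(
                [
                    make_record(
                        i,
                        protein="REV_X" if rng.random() < 0.4 else "X",
                        xcorr=float(rng.uniform(0, 5)),
                        delta_cn=float(rng.uniform(0, 0.5)),
                    )
                    for i in range(40)
                ]
            )
            _, uni = bide_search(records, ("xcorr",), 0.05)
            _, bi = bide_search(records, ("xcorr", "delta_cn"), 0.05)
            assert sum(not r.is_decoy for r in bi) >= sum(
                not r.is_decoy for r in uni
            )
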