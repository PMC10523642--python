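"""Replicate loop, exclusion accounting, and simulation summary metrics."""

import numpy as np
import pytest
from dataclasses import replace

from zicount import (
    FamilyFit,
    RegressionData,
    ReplicateRecord,
    SyntheticDataset,
    apply_exclusions,
    make_generative_model,
    preference_fraction,
    records_to_frame,
    run_replicate,
    run_scenario,
    simulate_dataset,
    summarize_metrics,
)
from zicount.model import ProfileInterval


def _toy_model(family="nb", beta0=0.9, r=0.5):
    model = make_generative_model("serious_illness", family)
    coeffs = (beta0,) + model.count_coefficients[1:]
    return replace(model, count_coefficients=coeffs, dispersion_r=r)


def _record(nb_aic, zinb_aic, est=-0.5, ci=None, conv=True):
    rec = ReplicateRecord(replicate_id=0, seed=0, n=422)
    for fam, aic in (("nb", nb_aic), ("zinb", zinb_aic)):
        rec.fits[fam] = FamilyFit(
            family=fam, estimate=est, aic=aic, llf=-aic / 2, converged=conv, ci=ci
        )
    return rec


class TestRunReplicate:
    def test_deterministic_rerun(self):
        model = _toy_model()
        ds = simulate_dataset(model, 150, master_seed=3, replicate_id=1)
        a = run_replicate(ds, compute_ci=False, replicate_id=1)
        b = run_replicate(ds, compute_ci=False, replicate_id=1)
        for fam in ("nb", "zinb"):
            assert a.fits[fam].estimate == b.fits[fam].estimate
            assert a.fits[fam].aic == b.fits[fam].aic

    def test_degenerate_arm_never_raises(self, rng):
        # all zeros in the treated arm: the likelihood for the treated mean
        # (or its structural-zero probability) is maximized at a boundary;
        # both fits must come back as flagged-or-extreme records, not errors
        n = 120
        trt = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        y = np.where(trt == 1, 0, rng.poisson(2.0, size=n))
        if not np.any(y > 0):
            y[0] = 1
        df = _frame(y, trt)
        df["risk2"] = rng.integers(0, 2, n)  # keep the design full rank
        data = RegressionData.from_dataframe(df)
        ds = SyntheticDataset(data=data, model=_toy_model(), seed=0)
        rec = run_replicate(ds, compute_ci=False)
        for fam in ("nb", "zinb"):
            ff = rec.fits[fam]
            degenerate = (
                ff.boundary_flag
                or not ff.converged
                or bool(ff.error)
                or ff.estimate < -5  # treated-arm mean driven to zero
            )
            assert degenerate

    def test_zinb_failure_isolated_from_nb(self, monkeypatch):
        # isolation contract: one family's hard failure leaves the other intact
        from zicount import harness as hmod

        real_from_data = hmod.CountModel.from_data.__func__

        def exploding(cls, data, family="nb"):
            if family == "zinb":
                raise RuntimeError("synthetic optimizer breakdown")
            return real_from_data(cls, data, family=family)

        monkeypatch.setattr(
            hmod.CountModel, "from_data", classmethod(exploding)
        )
        ds = simulate_dataset(_toy_model(), 150, master_seed=3, replicate_id=0)
        rec = run_replicate(ds, compute_ci=False)
        assert rec.fits["nb"].converged and np.isfinite(rec.fits["nb"].aic)
        assert rec.fits["zinb"].error and not rec.fits["zinb"].converged

    def test_record_aic_matches_independent_refit(self):
        from zicount import CountModel, model_aic

        ds = simulate_dataset(_toy_model(), 200, master_seed=8, replicate_id=0)
        rec = run_replicate(ds, compute_ci=False)
        refit = CountModel.from_data(ds.data, family="nb").fit()
        assert rec.fits["nb"].aic == pytest.approx(model_aic(refit), abs=1e-6)


def _frame(y, trt):
    import pandas as pd

    n = len(y)
    return pd.DataFrame(
        {
            "y": y,
            "treatment": trt,
            "age_ge2": np.tile([0, 1], n // 2),
            "risk2": 0,
            "risk3": 0,
            "offset_log": 0.0,
        }
    )


class TestApplyExclusions:
    def test_counts_and_rate(self):
        records = [_record(10, 11) for _ in range(97)] + [
            _record(10, 11, conv=False) for _ in range(3)
        ]
        kept, report = apply_exclusions(records, family="nb")
        assert len(kept) == 97
        assert report["per_family"]["nb"]["pct_excluded"] == pytest.approx(3.0)

    def test_no_flags_is_identity(self):
        records = [_record(10, 11) for _ in range(10)]
        kept, _ = apply_exclusions(records)
        assert kept == records

    def test_all_flagged_warns(self):
        records = [_record(10, 11, conv=False) for _ in range(4)]
        kept, report = apply_exclusions(records)
        assert kept == [] and "warning" in report

    def test_boundary_kept_by_default_dropped_on_request(self):
        rec = _record(10, 11)
        rec.fits["zinb"].boundary_flag = True
        kept_default, _ = apply_exclusions([rec], family="zinb")
        kept_strict, _ = apply_exclusions([rec], family="zinb", drop_boundary=True)
        assert len(kept_default) == 1 and len(kept_strict) == 0


class TestSummarizeMetrics:
    def test_perfect_estimates(self):
        recs = [_record(1, 2, est=-0.49) for _ in range(5)]
        s = summarize_metrics(recs, beta_dd=-0.49, family="nb")
        assert s.absolute_bias == 0.0 and s.mse == 0.0

    def test_hand_computed_values(self):
        recs = [_record(1, 2, est=-0.3), _record(1, 2, est=-0.7)]
        s = summarize_metrics(recs, beta_dd=-0.49, family="nb")
        assert s.absolute_bias == pytest.approx(0.20)
        assert s.mse == pytest.approx(0.0401)
        assert s.relative_bias == pytest.approx(0.20 / 0.49)

    def test_relative_bias_identity(self):
        recs = [_record(1, 2, est=e) for e in (-0.2, -0.5, -0.9)]
        s = summarize_metrics(recs, beta_dd=-0.64, family="nb")
        assert s.relative_bias == pytest.approx(s.absolute_bias / 0.64, abs=1e-9)

    def test_coverage_fraction(self):
        ci_in = ProfileInterval(-1.0, 0.0, 0.95)
        ci_out = ProfileInterval(0.1, 0.5, 0.95)
        recs = [_record(1, 2, ci=ci_in) for _ in range(19)] + [_record(1, 2, ci=ci_out)]
        s = summarize_metrics(recs, beta_dd=-0.49, family="nb")
        assert s.coverage == pytest.approx(0.95)

    def test_mse_dominates_squared_signed_bias(self, rng):
        ests = rng.normal(-0.5, 0.2, size=40)
        recs = [_record(1, 2, est=e) for e in ests]
        s = summarize_metrics(recs, beta_dd=-0.49, family="nb")
        assert s.mse >= s.mean_signed_bias**2 - 1e-12

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_metrics([_record(1, 2)], beta_dd=-0.49, family="nb")


class TestPreferenceFraction:
    def test_all_nb_better(self):
        assert preference_fraction([_record(10, 12)] * 5 ) == 1.0

    def test_ties_count_as_nb_preferred(self):
        assert preference_fraction([_record(10, 10)] * 4) == 1.0

    def test_mixed(self):
        recs = [_record(10, 12)] * 3 + [_record(12, 10)]
        assert preference_fraction(recs) == pytest.approx(0.75)

    def test_missing_aic_dropped_from_denominator(self):
        good = [_record(10, 12)] * 3
        bad = _record(np.nan, 12)
        assert preference_fraction(good + [bad]) == 1.0
        with pytest.raises(ValueError):
            preference_fraction([bad])


class TestScenario:
    def test_records_frame_shape_and_roundtrip_seeds(self):
        model = _toy_model()
        recs = run_scenario(model, n=100, reps=4, master_seed=5, compute_ci=False)
        df = records_to_frame(recs)
        assert len(df) == 8  # 4 replicates x 2 analysis families
        assert set(df["analysis_family"]) == {"nb", "zinb"}
        # each replicate regenerates in isolation from its index
        ds = simulate_dataset(model, 100, master_seed=5, replicate_id=2)
        again = run_replicate(ds, compute_ci=False, replicate_id=2)
        row = df[(df.replicate_id == 2) & (df.analysis_family == "nb")].iloc[0]
        assert row["estimate"] == pytest.approx(again.fits["nb"].estimate)

    def test_parallel_order_invariance(self):
        model = _toy_model()
        serial = run_scenario(model, n=100, reps=4, master_seed=9, compute_ci=False)
        par = run_scenario(model, n=100, reps=4, master_seed=9, compute_ci=False, n_jobs=2)
        for a, b in zip(serial, par):
            assert a.fits["nb"].estimate == b.fits["nb"].estimate

    def test_absolute_bias_shrinks_with_sample_size(self):
        # correctly specified NB analysis: estimation error falls as n grows
        model = _toy_model()
        maes = {}
        for n in (100, 800):
            recs = run_scenario(
                model, n=n, reps=150, master_seed=13,
                analysis_families=("nb",), compute_ci=False,
            )
            kept, _ = apply_exclusions(recs, family="nb")
            s = summarize_metrics(kept, beta_dd=model.beta_dd, family="nb")
            maes[n] = s.absolute_bias
        assert maes[800] < maes[100]
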