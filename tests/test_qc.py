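"""Sample QC gates, probe filtering, quantile normalization and the
variable-probe rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devmeth import BetaMatrix, SampleQcSummary, apply_sample_qc
from devmeth.qc import filter_probes, quantile_normalize, select_variable_probes


def _summary(sid="s1", meth=2500, unmeth=2400, fail=0.004, conv=96):
    return SampleQcSummary(sid, meth, unmeth, fail, conv)


class TestSampleQc:
    @pytest.mark.parametrize("kwargs, passed, reason", [
        (dict(), True, ""),
        (dict(conv=89.9), False, "bisulfite_conversion"),
        (dict(conv=90.0), True, ""),                   # 90 passes inclusively
        (dict(fail=0.02), False, "detection"),
        (dict(meth=1999), False, "intensity"),
        (dict(unmeth=1500), False, "intensity"),
    ])
    def test_gates(self, kwargs, passed, reason):
        res = apply_sample_qc([_summary(**kwargs)])
        assert bool(res["passed"].iloc[0]) is passed
        assert res["failed_criterion"].iloc[0] == reason


class TestProbeFiltering:
    @pytest.fixture
    def setup(self, tiny_manifest):
        beta = BetaMatrix(pd.DataFrame(
            0.5, index=tiny_manifest.probe_ids, columns=["s1", "s2", "s3"]))
        return beta, tiny_manifest

    def test_detection_fail_in_one_sample_retained(self, setup):
        beta, manifest = setup
        counts = pd.Series([1, 0, 0], index=beta.probe_ids)
        filtered, status = filter_probes(beta, manifest, counts)
        assert "cg01" in filtered.probe_ids
        assert status.loc["cg01", "removed_reason"] == "none"

    def test_detection_fail_in_two_samples_removed(self, setup):
        beta, manifest = setup
        counts = pd.Series([2, 0, 0], index=beta.probe_ids)
        filtered, status = filter_probes(beta, manifest, counts)
        assert "cg01" not in filtered.probe_ids
        assert status.loc["cg01", "removed_reason"] == "detection_fail"

    def test_chrom0_removed(self, setup):
        beta, manifest = setup
        manifest.table.loc["cg03", "chrom"] = "0"
        filtered, status = filter_probes(
            beta, manifest, pd.Series(0, index=beta.probe_ids))
        assert status.loc["cg03", "removed_reason"] == "chrom0"

    def test_flag_reasons_and_single_reason_each(self, setup):
        beta, manifest = setup
        manifest.table.loc["cg01", "flagged"] = True
        manifest.table.loc["cg02", "mfg_change_flagged"] = True
        _, status = filter_probes(beta, manifest,
                                  pd.Series(0, index=beta.probe_ids))
        assert status.loc["cg01", "removed_reason"] == "flagged_manifest"
        assert status.loc["cg02", "removed_reason"] == "mfg_change_flagged"

    def test_retained_set_order_independent(self, default_dataset):
        """The retained probes do not depend on which rule fires first:
        a probe matching several rules is removed regardless."""
        ds = default_dataset
        filtered, status = filter_probes(ds.beta, ds.manifest,
                                         ds.truth.detection_fail_counts)
        tab = ds.manifest.table
        fails = ds.truth.detection_fail_counts
        should_remove = (tab["flagged"] | tab["mfg_change_flagged"]
                         | (tab["chrom"] == "0") | (fails > 1))
        assert set(filtered.probe_ids) == set(tab.index[~should_remove])


class TestQuantileNormalize:
    def test_identical_value_multisets_unchanged(self):
        beta = BetaMatrix(pd.DataFrame({"s1": [0.1, 0.5, 0.9],
                                        "s2": [0.9, 0.1, 0.5]},
                                       index=["a", "b", "c"]))
        out = quantile_normalize(beta)
        assert sorted(out.data["s1"]) == sorted(beta.data["s1"])
        np.testing.assert_allclose(out.data.to_numpy(),
                                   beta.data.to_numpy(), atol=1e-12)

    def test_hand_computed_reference(self):
        # sorted columns: (0.0,0.4,0.8) and (0.2,0.6,1.0); reference mean
        # distribution = (0.1,0.5,0.9)
        beta = BetaMatrix(pd.DataFrame({"s1": [0.0, 0.4, 0.8],
                                        "s2": [1.0, 0.2, 0.6]},
                                       index=["a", "b", "c"]))
        out = quantile_normalize(beta)
        np.testing.assert_allclose(sorted(out.data["s1"]), [0.1, 0.5, 0.9])
        np.testing.assert_allclose(sorted(out.data["s2"]), [0.1, 0.5, 0.9])
        # ranks preserved within sample
        assert out.data.loc["a", "s2"] == 0.9

    def test_idempotent_on_tie_free_data(self):
        # exact fixed point holds for tie-free columns (continuous betas);
        # ties (e.g. from boundary clipping) are averaged and may shift
        # slightly on re-normalization
        rng = np.random.default_rng(3)
        beta = BetaMatrix(pd.DataFrame(
            rng.uniform(0, 1, (200, 8)),
            index=[f"p{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(8)]))
        once = quantile_normalize(beta)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.data.to_numpy(),
                                   twice.data.to_numpy(), atol=1e-12)

    def test_single_sample_identity_with_warning(self, caplog):
        beta = BetaMatrix(pd.DataFrame({"s1": [0.1, 0.9]}, index=["a", "b"]))
        with caplog.at_level("WARNING"):
            out = quantile_normalize(beta)
        assert out.data.equals(beta.data)
        assert any("identity" in r.message for r in caplog.records)

    def test_output_within_unit_interval(self, default_dataset):
        out = quantile_normalize(default_dataset.beta)
        vals = out.data.to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1


class TestVariableProbes:
    def test_constant_probe_not_variable(self):
        beta = BetaMatrix(pd.DataFrame(
            [[0.5] * 10], index=["a"], columns=[f"s{i}" for i in range(10)]))
        assert not select_variable_probes(beta)["a"]

    def test_full_span_probe_variable(self):
        vals = np.linspace(0, 1, 50)
        beta = BetaMatrix(pd.DataFrame(
            [vals], index=["a"], columns=[f"s{i}" for i in range(50)]))
        assert select_variable_probes(beta)["a"]

    def test_hand_computed_inner_80pct_range(self):
        # sorted betas 0.10..0.19 over 10 samples: q10 = 0.109, q90 = 0.181
        # (linear interpolation), inner range 0.072 > 0.05 -> variable
        vals = np.arange(0.10, 0.195, 0.01)
        beta = BetaMatrix(pd.DataFrame(
            [vals], index=["a"], columns=[f"s{i}" for i in range(10)]))
        assert select_variable_probes(beta)["a"]
        # same shape scaled to a total range of 0.04: inner range 0.032
        scaled = 0.10 + (vals - 0.10) * (0.04 / 0.09)
        beta2 = BetaMatrix(pd.DataFrame(
            [scaled], index=["a"], columns=[f"s{i}" for i in range(10)]))
        assert not select_variable_probes(beta2)["a"]

    def test_sample_order_invariance(self, default_dataset):
        beta = default_dataset.beta
        shuffled = beta.subset_samples(list(beta.sample_ids[::-1]))
        a = select_variable_probes(beta)
        b = select_variable_probes(shuffled)
        assert a.equals(b)

    @given(thr=st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_threshold(self, thr):
        rng = np.random.default_rng(0)
        beta = BetaMatrix(pd.DataFrame(
            rng.uniform(0, 1, (30, 12)),
            index=[f"p{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(12)]))
        strict = select_variable_probes(beta, min_range=thr + 0.05)
        loose = select_variable_probes(beta, min_range=thr)
        assert set(np.flatnonzero(strict)) <= set(np.flatnonzero(loose))
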