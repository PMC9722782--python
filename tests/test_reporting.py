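"""Wilcoxon signed-rank, paired comparison, anomaly scan, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gliofed import (
    LabelMap,
    RegionChannels,
    compare_models_paired,
    site_anomaly_scan,
    summarize,
    wilcoxon_signed_rank,
)
from gliofed.federation import RoundRecord
from gliofed.labels import derive_region_channels
from gliofed.phantom import Case


def enumerate_exact_p(diffs):
    """Brute force over all 2^n sign assignments of |d| midranks:
    p = min(1, 2*min(P(W <= w), P(W >= w)))."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.dot(ranks, signs) for signs in itertools.product([0, 1], repeat=len(d))]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0 and res.method == "degenerate" and res.note

    def test_all_positive_n5_exact(self):
        """Five uniformly positive differences: p = 2 * (1/2^5) = 0.0625."""
        res = wilcoxon_signed_rank(np.arange(1.0, 6.0), np.zeros(5))
        assert res.p == pytest.approx(0.0625, abs=1e-12)
        assert res.method == "exact"

    @pytest.mark.parametrize("n", range(2, 13))
    def test_exact_matches_enumeration(self, n):
        """The exact branch agrees with full sign-assignment enumeration for
        every n <= 12, including tied absolute differences."""
        rng = np.random.default_rng(n)
        x = np.round(rng.normal(size=n), 1)
        y = np.round(x + rng.normal(0.2, 0.6, size=n), 1)
        d = x - y
        if np.all(d == 0):
            return
        res = wilcoxon_signed_rank(x, y)
        assert res.p == pytest.approx(enumerate_exact_p(d), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            x = rng.normal(size=10)
            y = x + rng.normal(0.3, 1.0, size=10)
            ours = wilcoxon_signed_rank(x, y).p
            ref = float(sps.wilcoxon(x, y, zero_method="wilcox", method="exact").pvalue)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = x + rng.normal(0.5, 1.0, size=40)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "approx" and 0.0 <= res.p <= 1.0

    def test_zero_differences_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 2.0, 3.0, 4.0])  # two zero differences
        res = wilcoxon_signed_rank(x, y)
        assert res.n_used == 3


class ConstModel:
    def __init__(self, channels):
        self.channels = np.asarray(channels, float)

    def __call__(self, image):
        return RegionChannels(self.channels.copy(), kind="binary")


def tiny_cases(n=4):
    cases = []
    for i in range(n):
        lbl = np.zeros((6, 6, 6), dtype=np.int16)
        lbl[1:5, 1:5, 1:5] = 2
        lbl[2:4, 2:4, 2:4] = 4
        img = np.ones((4, 6, 6, 6), dtype=np.float32)
        cases.append(Case(f"c{i}", "s", img, LabelMap(lbl)))
    return cases


class TestCompareModelsPaired:
    def test_equal_models_zero_improvement(self):
        cases = tiny_cases()
        ref = derive_region_channels(cases[0].labels)
        model = ConstModel(ref.channels)
        rep = compare_models_paired(model, model, cases)
        for c in ("dsc_et", "dsc_tc", "dsc_wt"):
            assert rep.improvement_pct[c] == 0.0
            assert rep.p[c].p == 1.0
        assert rep.n_cases == 4

    def test_relative_improvement_arithmetic(self):
        """mean_A = 0.62 to mean_B = 0.8246 is a +33% relative gain."""
        assert (0.8246 - 0.62) / 0.62 * 100 == pytest.approx(33.0, abs=0.01)

    def test_zero_baseline_guarded_not_infinite(self):
        cases = tiny_cases()
        ref = derive_region_channels(cases[0].labels)
        zeros = ConstModel(np.zeros_like(ref.channels))
        oracle = ConstModel(ref.channels)
        rep = compare_models_paired(zeros, oracle, cases)
        assert all(v is None for v in rep.improvement_pct.values())
        assert all(rep.mean_b[c] == 1.0 for c in rep.mean_b)

    def test_antisymmetric_orientation(self):
        cases = tiny_cases()
        ref = derive_region_channels(cases[0].labels)
        good = ConstModel(ref.channels)
        worse = ConstModel(np.roll(ref.channels, 1, axis=1))
        fwd = compare_models_paired(worse, good, cases)
        rev = compare_models_paired(good, worse, cases)
        for c in ("dsc_et", "dsc_tc", "dsc_wt"):
            # signs flip; magnitudes differ only through the denominator
            assert fwd.improvement_pct[c] > 0 > rev.improvement_pct[c]
            assert fwd.mean_a[c] == rev.mean_b[c] and fwd.mean_b[c] == rev.mean_a[c]


def synthetic_history(site_offsets, n_rounds=12, seed=0):
    """Round records where each site's mean tracks the federation mean plus
    a fixed offset and small noise."""
    rng = np.random.default_rng(seed)
    cols = ("dsc_et", "dsc_tc", "dsc_wt")
    history = []
    for r in range(n_rounds):
        base = 0.5 + 0.3 * (1 - np.exp(-r / 4))
        site_means = {}
        for site, off in site_offsets.items():
            site_means[site] = {
                **{c: float(np.clip(base + off + rng.normal(0, 0.01), 0, 1))
                   for c in cols},
                "n_val": 2,
            }
        pooled = {c: float(np.mean([m[c] for m in site_means.values()])) for c in cols}
        history.append(RoundRecord(
            round=r, site_means=site_means, site_losses={s: 0.1 for s in site_means},
            pooled_region=pooled,
            pooled_collective=float(np.mean(list(pooled.values()))),
            per_case=pd.DataFrame(
                [(f"{s}_c", s, r, m["dsc_et"], m["dsc_tc"], m["dsc_wt"])
                 for s, m in site_means.items()],
                columns=["case", "site", "round", "dsc_et", "dsc_tc", "dsc_wt"],
            ),
        ))
    return history


class TestSiteAnomalyScan:
    def test_site_tracking_federation_not_flagged(self):
        hist = synthetic_history({"a": 0.0, "b": 0.0, "c": 0.0}, seed=1)
        rep = site_anomaly_scan(hist, "a")
        assert not rep.flagged

    def test_depressed_site_flagged(self):
        hist = synthetic_history({"a": 0.0, "b": 0.0, "bad": -0.2}, seed=2)
        rep = site_anomaly_scan(hist, "bad")
        assert rep.flagged
        assert all(rep.p[c].p < 0.05 for c in rep.p)

    def test_high_site_never_flagged(self):
        """A site uniformly above the federation mean is not an anomaly even
        though its Wilcoxon p is significant."""
        hist = synthetic_history({"a": 0.0, "b": 0.0, "hi": +0.15}, seed=3)
        rep = site_anomaly_scan(hist, "hi")
        assert any(r.p < 0.05 for r in rep.p.values())
        assert not rep.flagged

    def test_unknown_site_rejected(self):
        hist = synthetic_history({"a": 0.0, "b": 0.0})
        with pytest.raises(KeyError, match="nope"):
            site_anomaly_scan(hist, "nope")


class TestSummarize:
    def test_report_files_and_recomputation(self, tmp_path):
        hist = synthetic_history({"a": 0.0, "b": -0.1}, n_rounds=5)
        anomalies = [site_anomaly_scan(hist, s) for s in ("a", "b")]
        out = summarize(hist, tmp_path / "rep", anomalies=anomalies)
        curves = pd.read_csv(out / "round_curves.csv")
        per_case = pd.read_csv(out / "per_case_scores.csv")
        # row count: rounds x (sites + 1 pooled)
        assert len(curves) == 5 * 3
        # pooled curve rows re-derive from the per-case table
        for r in range(5):
            pooled = curves[(curves["round"] == r) & (curves["site"] == "pooled")].iloc[0]
            sub = per_case[per_case["round"] == r]
            assert pooled["dsc_et"] == pytest.approx(sub["dsc_et"].mean(), abs=1e-9)
        anoms = pd.read_csv(out / "anomalies.csv")
        assert set(anoms["site"]) == {"a", "b"}

    def test_empty_reports_header_only(self, tmp_path):
        hist = synthetic_history({"a": 0.0, "b": 0.0}, n_rounds=3)
        out = summarize(hist, tmp_path / "rep")
        comp = pd.read_csv(out / "comparisons.csv")
        assert comp.empty and "improvement_pct" in comp.columns
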