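"""Paired model comparison, Wilcoxon signed-rank tests, anomaly scanning.

Two uses mirror the study protocol: (i) comparing a trained consensus
model with the initial model on the same cases, reporting per-region
relative improvement percentages with paired Wilcoxon p-values; (ii)
flagging sites whose per-round local validation scores sit significantly
below the federation-wide mean — how annotation-quality problems at a
site are surfaced without ever seeing its data.

The signed-rank test drops zero differences, uses the exact null
distribution (dynamic programming over signed midranks, so ties are
handled) for up to 25 remaining pairs, and a normal approximation with
continuity and tie corrections beyond that. Tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .federation import REGION_COLS, history_to_frame, per_case_frame
from .metrics import evaluate_case

__all__ = [
    "WilcoxonResult", "ComparisonReport", "AnomalyReport",
    "wilcoxon_signed_rank", "compare_models_paired", "site_anomaly_scan",
    "summarize",
]

EXACT_MAX_N = 25


@dataclass
class WilcoxonResult:
    p: float
    statistic: float  # W+ = sum of ranks of positive differences
    n_used: int  # pairs remaining after dropping zero differences
    method: str  # 'exact' | 'approx' | 'degenerate'
    note: str = ""

    def __float__(self) -> float:
        return self.p


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p via the null distribution of W+.

    Midranks are doubled to integers; the distribution over all 2^n sign
    assignments is built by convolution. p = min(1, 2·min(P(W ≤ w),
    P(W ≥ w))).
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_p(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with continuity correction and tie correction."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    d = w_plus - mu
    cc = 0.5 * np.sign(d)
    z = (d - cc) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Two-sided paired signed-rank test of ``x`` vs ``y``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 1:
        raise ValueError("need at least one pair")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(p=1.0, statistic=0.0, n_used=0, method="degenerate",
                              note="all paired differences are zero")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= EXACT_MAX_N:
        return WilcoxonResult(p=_exact_p(ranks, w_plus), statistic=w_plus,
                              n_used=int(d.size), method="exact")
    return WilcoxonResult(p=_approx_p(ranks, w_plus), statistic=w_plus,
                          n_used=int(d.size), method="approx")


@dataclass
class ComparisonReport:
    """Paired A-vs-B evaluation over one case set."""

    mean_a: dict  # region col -> mean DSC of model A
    mean_b: dict
    improvement_pct: dict  # region col -> (mean_b - mean_a)/mean_a * 100, or None
    p: dict  # region col -> WilcoxonResult
    n_cases: int
    per_case: pd.DataFrame = field(repr=False, default=None)


def compare_models_paired(predict_a, predict_b, cases) -> ComparisonReport:
    """Per-region paired DSC comparison of two predictors on shared cases.

    Improvement is relative: (mean_B − mean_A) / mean_A × 100 per region;
    a zero baseline mean yields ``None`` (undefined), never infinity.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("need at least one case")
    rows = []
    for case in cases:
        sa = evaluate_case(predict_a, case)
        sb = evaluate_case(predict_b, case)
        rows.append((case.case_id, *sa.as_tuple(), *sb.as_tuple()))
    cols = ["case"] + [f"a_{c}" for c in REGION_COLS] + [f"b_{c}" for c in REGION_COLS]
    frame = pd.DataFrame(rows, columns=cols)
    mean_a = {c: float(frame[f"a_{c}"].mean()) for c in REGION_COLS}
    mean_b = {c: float(frame[f"b_{c}"].mean()) for c in REGION_COLS}
    improvement = {
        c: None if mean_a[c] == 0 else (mean_b[c] - mean_a[c]) / mean_a[c] * 100.0
        for c in REGION_COLS
    }
    pvals = {
        c: wilcoxon_signed_rank(frame[f"b_{c}"].to_numpy(), frame[f"a_{c}"].to_numpy())
        for c in REGION_COLS
    }
    return ComparisonReport(mean_a=mean_a, mean_b=mean_b, improvement_pct=improvement,
                            p=pvals, n_cases=len(cases), per_case=frame)


@dataclass
class AnomalyReport:
    """Round-wise comparison of one site against the federation mean."""

    site_id: str
    site_series: pd.DataFrame  # rounds x region cols
    federation_series: pd.DataFrame
    p: dict  # region col -> WilcoxonResult
    region_flagged: dict  # region col -> bool
    alpha: float
    min_deficit: float = 0.0

    @property
    def flagged(self) -> bool:
        return any(self.region_flagged.values())


def site_anomaly_scan(history, site_id: str, alpha: float = 0.05,
                      min_deficit: float = 0.05) -> AnomalyReport:
    """Flag a site whose validation scores run significantly *below* the
    federation mean: paired per-round Wilcoxon per region, two-sided, with
    the flag additionally requiring the site mean to sit at least
    ``min_deficit`` DSC under the federation mean.

    The margin makes the flag a *practical*-significance rule: because the
    per-round site and federation curves move together (they score the
    same consensus model), any persistent case-difficulty offset — however
    small — yields a tiny paired p-value over enough rounds. Annotation
    problems produce deficits an order of magnitude above ordinary
    between-site difficulty differences, so the default margin of 0.05 DSC
    separates the two regimes; pass 0.0 for the purely statistical rule.
    High-scoring sites are never anomalies."""
    if len(history) < 2:
        raise ValueError("need at least 2 rounds for an anomaly scan")
    known = set(history[0].site_means)
    if site_id not in known:
        raise KeyError(f"unknown site {site_id!r}; sites: {sorted(known)}")
    rounds = [rec.round for rec in history]
    site_rows, fed_rows = [], []
    for rec in history:
        site_rows.append({c: rec.site_means[site_id][c] for c in REGION_COLS})
        fed_rows.append(dict(rec.pooled_region))
    site_series = pd.DataFrame(site_rows, index=rounds)
    fed_series = pd.DataFrame(fed_rows, index=rounds)
    p, flagged = {}, {}
    for c in REGION_COLS:
        res = wilcoxon_signed_rank(site_series[c].to_numpy(), fed_series[c].to_numpy())
        p[c] = res
        flagged[c] = bool(
            res.p < alpha
            and site_series[c].mean() < fed_series[c].mean() - min_deficit
        )
    return AnomalyReport(site_id=site_id, site_series=site_series,
                         federation_series=fed_series, p=p,
                         region_flagged=flagged, alpha=alpha, min_deficit=min_deficit)


def summarize(history, out_dir, comparisons=(), anomalies=(), bonferroni: bool = False):
    """Emit the run's report files: round curves, per-case scores, and the
    comparison/anomaly tables. Every summary number is re-derivable from
    the per-case CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    history_to_frame(history).to_csv(out / "round_curves.csv", index=False)
    per_case_frame(history).to_csv(out / "per_case_scores.csv", index=False)

    comp_rows = []
    for name, rep in comparisons:
        for c in REGION_COLS:
            comp_rows.append({
                "comparison": name, "region": c.removeprefix("dsc_").upper(),
                "mean_a": rep.mean_a[c], "mean_b": rep.mean_b[c],
                "improvement_pct": rep.improvement_pct[c],
                "p": rep.p[c].p, "method": rep.p[c].method, "n_cases": rep.n_cases,
            })
    comp_cols = ["comparison", "region", "mean_a", "mean_b",
                 "improvement_pct", "p", "method", "n_cases"]
    pd.DataFrame(comp_rows, columns=comp_cols).to_csv(out / "comparisons.csv", index=False)

    anom_rows = []
    n_tests = max(1, len(list(anomalies)) * len(REGION_COLS))
    for rep in anomalies:
        for c in REGION_COLS:
            row = {
                "site": rep.site_id, "region": c.removeprefix("dsc_").upper(),
                "site_mean": rep.site_series[c].mean(),
                "federation_mean": rep.federation_series[c].mean(),
                "p": rep.p[c].p, "flagged": rep.region_flagged[c], "alpha": rep.alpha,
            }
            if bonferroni:
                row["p_bonferroni"] = min(1.0, rep.p[c].p * n_tests)
            anom_rows.append(row)
    anom_cols = ["site", "region", "site_mean", "federation_mean", "p", "flagged", "alpha"]
    if bonferroni:
        anom_cols.append("p_bonferroni")
    pd.DataFrame(anom_rows, columns=anom_cols).to_csv(out / "anomalies.csv", index=False)
    return out
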