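"""Paired statistical protocol for the with/without-correction comparison.

Records are paired on (sphere, amplitude, TBR) — 6 x 5 x 3 = 90 pairs under
the default design — and, per parameter (RC_max, RC_mean, CNR_max,
CNR_mean), the paired differences are tested:

1. Shapiro-Wilk on the differences (with a quantile-quantile summary table
   for visual checking);
2. paired t-test when normality is not rejected at ``alpha_normality``,
   otherwise the Wilcoxon signed-rank test.

Wilcoxon conventions: zero differences are dropped (Wilcoxon's original
treatment) and the reported n counts the pairs actually entering the test;
the statistic W is the smaller of the two signed-rank sums; the p-value is
exact for n <= 25 and a normal approximation (no continuity correction)
above that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import PARAMETERS

WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class StatResult:
    parameter: str
    n: int                   # pairs entering the test (after zero handling)
    normality_p: float
    test_used: str           # 'paired_t' | 'wilcoxon_signed_rank' | 'degenerate'
    statistic: float
    p_value: float


def pair_records(records: pd.DataFrame,
                 parameters: tuple[str, ...] = PARAMETERS) -> pd.DataFrame:
    """Paired (with - without) differences per design cell and parameter.

    Returns one row per (sphere, amplitude, TBR) cell with a difference
    column per parameter; raises naming the cell if either member of a pair
    is missing.
    """
    keys = ["sphere_volume_ml", "amplitude", "tbr"]
    out = None
    for p in parameters:
        wide = records.pivot_table(index=keys, columns="corrected", values=p,
                                   aggfunc="first")
        for flag in (True, False):
            if flag not in wide.columns:
                raise ValueError(f"no records with corrected={flag}")
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        if bad:
            raise ValueError(f"incomplete with/without pair for cells {bad}")
        diff = (wide[True] - wide[False]).rename(f"d_{p}")
        out = diff.to_frame() if out is None else out.join(diff)
    return out.reset_index()


def qq_table(differences: np.ndarray, n_quantiles: int = 20) -> pd.DataFrame:
    """Sample vs theoretical-normal quantiles of the paired differences."""
    d = np.sort(np.asarray(differences, dtype=float))
    probs = (np.arange(1, n_quantiles + 1) - 0.5) / n_quantiles
    sample_q = np.quantile(d, probs)
    theo_q = sps.norm.ppf(probs, loc=d.mean(), scale=d.std(ddof=1))
    return pd.DataFrame({"prob": probs, "sample_quantile": sample_q,
                         "normal_quantile": theo_q})


def wilcoxon_signed_rank(differences: np.ndarray) -> tuple[float, float, int]:
    """Two-sided signed-rank test; returns (W, p, n after dropping zeros).

    W is the smaller of the positive- and negative-rank sums.  Exact null
    distribution for small n without ties, normal approximation otherwise.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the signed-rank test is undefined")
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= WILCOXON_EXACT_MAX_N and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       correction=False, method=method)
    return float(res.statistic), float(res.pvalue), n


def choose_and_run_test(differences: np.ndarray,
                        alpha_normality: float = 0.05,
                        parameter: str = "") -> StatResult:
    """Shapiro-Wilk gate, then paired t-test or Wilcoxon signed-rank."""
    d = np.asarray(differences, dtype=float)
    if np.all(d == 0):
        return StatResult(parameter=parameter, n=d.size, normality_p=np.nan,
                          test_used="degenerate", statistic=np.nan, p_value=np.nan)
    if d.size < 8:
        raise ValueError(f"need at least 8 pairs for the normality gate, got {d.size}")
    sw = sps.shapiro(d)
    if sw.pvalue >= alpha_normality:
        t = sps.ttest_1samp(d, popmean=0.0)
        return StatResult(parameter=parameter, n=d.size,
                          normality_p=float(sw.pvalue), test_used="paired_t",
                          statistic=float(t.statistic), p_value=float(t.pvalue))
    w, p, n = wilcoxon_signed_rank(d)
    return StatResult(parameter=parameter, n=n, normality_p=float(sw.pvalue),
                      test_used="wilcoxon_signed_rank", statistic=w, p_value=p)


def run_statistical_report(records: pd.DataFrame,
                           alpha_normality: float = 0.05,
                           parameters: tuple[str, ...] = PARAMETERS,
                           ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """One test per parameter on the paired differences.

    Returns a one-row-per-parameter results table and, per parameter, the
    quantile-quantile summary used for the normality check.
    """
    paired = pair_records(records, parameters)
    rows, qq = [], {}
    for p in parameters:
        d = paired[f"d_{p}"].to_numpy()
        if np.isnan(d).any() or (d.size < 8 and not np.all(d == 0)):
            # undefined endpoint (e.g. CNR on a noise-free image) or too few
            # pairs for the normality gate: report, but run no test
            rows.append(StatResult(parameter=p, n=int(np.sum(~np.isnan(d))),
                                   normality_p=np.nan, test_used="undefined",
                                   statistic=np.nan, p_value=np.nan).__dict__)
            continue
        res = choose_and_run_test(d, alpha_normality, parameter=p)
        rows.append(res.__dict__)
        if np.std(d) > 0:
            qq[p] = qq_table(d)
    return pd.DataFrame(rows), qq


def format_report(results: pd.DataFrame) -> str:
    """Plain-text report, one line per parameter."""
    lines = []
    for _, r in results.iterrows():
        if r["test_used"] == "degenerate":
            lines.append(f"{r['parameter']}: all paired differences zero "
                         f"(n = {r['n']}); no test performed")
            continue
        if r["test_used"] == "undefined":
            lines.append(f"{r['parameter']}: undefined differences "
                         "(endpoint not computable on this input); no test performed")
            continue
        stat_name = "t" if r["test_used"] == "paired_t" else "W"
        lines.append(
            f"{r['parameter']}: {r['test_used']} "
            f"({stat_name} = {r['statistic']:.4g}, p = {r['p_value']:.3g}, "
            f"n = {r['n']}; Shapiro-Wilk p = {r['normality_p']:.3g})")
    return "\n".join(lines)
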