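"""Taxa-phenotype association statistics and false-discovery-rate control.

Per-taxon tests are rank-based (Kruskal-Wallis across two or more phenotype
levels, Wilcoxon rank-sum for two groups), so they make no normality
assumption about compositional relative abundances.  Multiplicity across taxa
is controlled with Storey q-values: the proportion of truly null features
pi0 is estimated from the flat right tail of the p-value histogram,

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)),

smoothed with a least-squares cubic fit over a lambda grid and read off at
the largest lambda, then

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j

over the sorted p-values.  With pi0 = 1 this reduces exactly to
Benjamini-Hochberg.  Effect sizes for two-level labels are Cohen's d
(pooled-SD standardized mean difference; Cliff's delta available as an
alternative), signed so positive means enriched in the case group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .abundance import AbundanceTable

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p across >= 2 groups (mid-ranks for ties).

    All-identical values yield ``(0.0, 1.0)`` by convention (the tie
    correction is degenerate there).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels")
    samples = []
    for lev in levels:
        x = values[groups == lev]
        if len(x) == 0:
            raise ValueError(f"group {lev!r} has no observations")
        samples.append(x)
    if len(values) < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact enumeration when the pooled size is <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    Returns ``(U_a, p)`` where ``U_a`` counts pairs won by the first group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def estimate_pi0(pvalues, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Storey's pi0: cubic fit of pi0(lambda) over the grid, read at max lambda.

    Clamped into (0, 1].  With fewer than 100 p-values the tail estimate is
    unstable; a warning is issued and pi0 = 1 (Benjamini-Hochberg behavior)
    is returned.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-d array of p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m < 100:
        warnings.warn("fewer than 100 p-values: pi0 estimate unstable, using pi0=1")
        return 1.0
    grid = np.asarray(lambda_grid, dtype=float)
    raw = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in grid])
    if len(grid) < 4:
        # too few grid points for a cubic; use the raw tail estimate
        pi0 = float(raw[np.argmax(grid)])
    else:
        # raw pi0(lambda) has variance ~ pi0 / (m (1 - lambda)); weight the
        # least-squares fit by the inverse standard deviation
        coef = np.polynomial.polynomial.polyfit(grid, raw, deg=3,
                                                w=np.sqrt(1.0 - grid))
        pi0 = float(np.polynomial.polynomial.polyval(grid.max(), coef))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(pvalues, lambda_grid=DEFAULT_LAMBDA_GRID,
                   pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values and the shared pi0 estimate.

    ``pi0`` may be pinned (e.g. to 1.0 for plain Benjamini-Hochberg); when
    None it is estimated from the p-value distribution.
    """
    p = np.asarray(pvalues, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value set")
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)


def fdr_diagnostics(pvalues, qvalues, pi0: float,
                    cutoffs: np.ndarray | None = None) -> dict[str, pd.DataFrame]:
    """Diagnostic curves for the FDR adjustment.

    Returns plot-ready tables: q-value vs p-value, number of significant
    features vs q cutoff, and expected false positives vs number called
    significant.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.asarray(qvalues, dtype=float)
    order = np.argsort(p)
    if cutoffs is None:
        cutoffs = np.linspace(0.0, 1.0, 101)
    n_sig = np.array([(q <= c).sum() for c in cutoffs])
    return {
        "q_vs_p": pd.DataFrame({"p": p[order], "q": q[order]}),
        "significant_vs_cutoff": pd.DataFrame({"q_cutoff": cutoffs, "n_significant": n_sig}),
        "expected_false_positives": pd.DataFrame(
            {"n_significant": n_sig, "expected_fp": cutoffs * n_sig}),
    }


def cohens_delta(case, control) -> float:
    """Cohen's d: (mean_case - mean_control) / pooled SD.

    Positive values mean enrichment in the case group.  Degenerate pooled SD
    returns 0 for equal means and signed infinity otherwise.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least 2 observations")
    diff = x.mean() - y.mean()
    pooled_var = (((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
                  / (len(x) + len(y) - 2))
    if pooled_var == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled_var))


def cliffs_delta(case, control) -> float:
    """Cliff's delta: P(X > Y) - P(X < Y) over all case/control pairs."""
    x = np.asarray(case, dtype=float)[:, None]
    y = np.asarray(control, dtype=float)[None, :]
    return float(((x > y).mean() - (x < y).mean()))


def associate_features(
    table: AbundanceTable,
    label_field: str,
    q_threshold: float = 0.05,
    effect: str = "cohen",
    case_level: str | None = None,
    pi0: float | None = None,
    include_zero_depth: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Per-feature Kruskal-Wallis association with a phenotype label.

    Runs on relative frequencies (normalizing first if needed), applies the
    Storey adjustment across features and, for two-level labels, computes a
    signed effect size (positive = enriched in the case level; the case level
    is ``case_level`` or the last level in sorted order).  Constant features
    get p = 1, effect 0 and a ``constant`` flag.

    Returns ``(results, pi0_hat)`` with results sorted by q ascending.
    """
    from .abundance import normalize

    if label_field not in table.metadata.columns:
        raise ValueError(f"metadata field {label_field!r} not found")
    if table.frequencies is None:
        table = normalize(table)
    freq = table.frequencies
    keep = list(table.samples)
    if not include_zero_depth:
        zero = set(table.zero_depth_samples())
        keep = [s for s in keep if s not in zero]
    labels = table.metadata.loc[keep, label_field]
    if labels.isna().any():
        raise ValueError(f"label {label_field!r} missing for samples "
                         f"{list(labels.index[labels.isna()])}")
    freq = freq[keep]
    levels = sorted(map(str, pd.unique(labels.astype(str))))
    two_level = len(levels) == 2
    if case_level is None and two_level:
        case_level = levels[-1]

    eff_fn = {"cohen": cohens_delta, "cliff": cliffs_delta}[effect]
    rows = []
    for feat in freq.index:
        v = freq.loc[feat].to_numpy(dtype=float)
        constant = bool(np.all(v == v[0]))
        if constant:
            h, p = 0.0, 1.0
        else:
            h, p = kruskal_wallis(v, labels.to_numpy())
        row = {"feature": feat, "H": h, "p": p, "constant": constant}
        for lev in levels:
            row[f"mean_{lev}"] = float(v[(labels.astype(str) == lev).to_numpy()].mean())
        if two_level:
            case = v[(labels.astype(str) == case_level).to_numpy()]
            ctrl = v[(labels.astype(str) != case_level).to_numpy()]
            d = 0.0 if constant else eff_fn(case, ctrl)
            row["delta"] = d
            row["direction"] = ("case" if d > 0 else "control" if d < 0 else "none")
        rows.append(row)
    res = pd.DataFrame(rows).set_index("feature")
    q, pi0_hat = storey_qvalues(res["p"].to_numpy(), pi0=pi0)
    res["q"] = q
    res["pi0_hat"] = pi0_hat
    res["significant"] = res["q"] < q_threshold
    return res.sort_values(["q", "p"]), pi0_hat
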