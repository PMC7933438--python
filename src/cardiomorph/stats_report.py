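"""Study-level statistics and report assembly.

Group endpoints (chamber volume, conicity, zone vascular densities,
echocardiographic percent changes, ...) are compared by one-way ANOVA with
Tukey-Kramer post-hoc adjustment (the unequal-n form of Tukey's honest
significant difference, using the studentized-range distribution), plus
plain two-tailed t-tests for pre-specified pairs and Pearson correlation
for cross-modality agreement.  Values are summarised as mean ± s.e.m.
No correction is applied across endpoints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_TABLE_COLUMNS = ("subject", "group", "endpoint", "value", "units")


def percent_change(week0: float, week4: float, baseline: str = "week0") -> float:
    """Percent change of an echocardiographic value over the study period.

    Default: ``100 * (week4 - week0) / week0``.  ``baseline="week4"``
    selects the alternative normalisation by the terminal value,
    ``100 * (week4 - week0) / week4``; both denominators appear in the
    echocardiography literature, so the choice is explicit.
    """
    week0 = np.asarray(week0, float)
    week4 = np.asarray(week4, float)
    denom = week0 if baseline == "week0" else week4
    if baseline not in ("week0", "week4"):
        raise ValueError("baseline must be 'week0' or 'week4'")
    if np.any(denom == 0):
        raise ZeroDivisionError("percent change undefined for zero baseline")
    out = 100.0 * (week4 - week0) / denom
    return float(out) if out.ndim == 0 else out


@dataclass
class ComparisonResult:
    """One endpoint's group comparison: ANOVA, Tukey-Kramer, t-tests.

    ``ttests`` are plain two-sample two-tailed t-tests per pair;
    ``lsd`` are the unadjusted pairwise tests on the pooled ANOVA error
    (Fisher LSD) — the Tukey-Kramer adjusted p is never below the LSD p
    for the same pair, since both share the pooled standard error.
    """

    endpoint: str
    anova_f: float
    anova_p: float
    group_stats: dict[str, dict]          # label -> {mean, sem, n}
    tukey: dict[tuple[str, str], dict]    # pair -> {diff, q, p_adj}
    ttests: dict[tuple[str, str], dict]   # pair -> {t, p}
    lsd: dict[tuple[str, str], dict] = field(default_factory=dict)


def make_group_table(records: Sequence[Mapping] | pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format endpoint table (subject, group, endpoint, value, units)."""
    df = pd.DataFrame(records)
    missing = [c for c in GROUP_TABLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"group table missing columns: {missing}")
    if "units" not in df.columns:
        df["units"] = ""
    dup = df.duplicated(subset=["subject", "endpoint"])
    if dup.any():
        raise ValueError("more than one value per (subject, endpoint)")
    return df[list(GROUP_TABLE_COLUMNS)]


def tukey_kramer(groups: Mapping[str, np.ndarray]) -> dict[tuple[str, str], dict]:
    """Tukey-Kramer adjusted pairwise comparisons (unequal group sizes).

    For groups i, j with pooled within-group variance ``MSE`` on ``N - k``
    degrees of freedom, the studentized range statistic is
    ``q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))`` and the adjusted p
    is the survival function of the studentized range distribution with k
    groups and N - k degrees of freedom.
    """
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = {g: len(groups[g]) for g in labels}
    if any(n < 2 for n in ns.values()):
        raise ValueError("each group needs n >= 2")
    N = sum(ns.values())
    means = {g: float(np.mean(groups[g])) for g in labels}
    sse = sum(float(np.sum((np.asarray(groups[g]) - means[g]) ** 2)) for g in labels)
    df = N - k
    mse = sse / df
    if mse <= 0:
        raise ValueError("zero within-group variance: Tukey-Kramer undefined")
    out = {}
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(means[a] - means[b]) / se
        p = float(sps.studentized_range.sf(q, k, df))
        out[(a, b)] = {"diff": means[b] - means[a], "q": float(q), "p_adj": min(p, 1.0)}
    return out


def group_compare(
    table: pd.DataFrame,
    endpoint: str,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> ComparisonResult:
    """One-way ANOVA with Tukey-Kramer post hoc for one endpoint.

    ``pairs`` optionally restricts the plain two-tailed t-tests to
    pre-specified group pairs (default: all pairs).
    """
    sub = table[table["endpoint"] == endpoint]
    if sub.empty:
        raise ValueError(f"no rows for endpoint {endpoint!r}")
    groups = {
        g: np.asarray(v["value"], float) for g, v in sub.groupby("group", sort=False)
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f, p = sps.f_oneway(*groups.values())
    stats = {
        g: {
            "mean": float(np.mean(v)),
            "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))),
            "n": int(len(v)),
        }
        for g, v in groups.items()
    }
    tk = tukey_kramer(groups)
    if pairs is None:
        pairs = list(tk)
    tt = {}
    for a, b in pairs:
        t, pt = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        tt[(a, b)] = {"t": float(t), "p": float(pt)}
    # Fisher LSD: unadjusted pairwise t on the pooled within-group variance
    ns = {g: len(v) for g, v in groups.items()}
    N, k = sum(ns.values()), len(groups)
    mse = sum(
        float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in groups.values()
    ) / (N - k)
    lsd = {}
    for a, b in tk:
        se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        t = abs(stats[a]["mean"] - stats[b]["mean"]) / se
        lsd[(a, b)] = {"t": float(t), "p": float(2 * sps.t.sf(t, N - k))}
    return ComparisonResult(endpoint, float(f), float(p), stats, tk, tt, lsd)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-tailed p from the t distribution."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def build_report(
    table: pd.DataFrame,
    out_dir: str | Path,
    endpoints: Sequence[str] | None = None,
    make_plots: bool = False,
) -> dict:
    """Write per-endpoint CSVs, a JSON study summary and optional plots.

    Returns the summary dictionary (group means ± s.e.m., ANOVA and
    Tukey-Kramer p-values per endpoint) that is also written to
    ``summary.json``.
    """
    from .volume_io import save_json

    if table is None or len(table) == 0:
        raise ValueError("empty endpoint table")
    table = make_group_table(table)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if endpoints is None:
        endpoints = list(table["endpoint"].unique())
    summary = {}
    for ep in endpoints:
        sub = table[table["endpoint"] == ep]
        safe = ep.replace("/", "_").replace(" ", "_")
        sub.to_csv(out_dir / f"{safe}.csv", index=False)
        entry = {"units": str(sub["units"].iloc[0])}
        if sub["group"].nunique() >= 2 and (sub.groupby("group").size() >= 2).all():
            res = group_compare(table, ep)
            entry.update(
                anova_f=res.anova_f,
                anova_p=res.anova_p,
                groups=res.group_stats,
                tukey={f"{a} vs {b}": d for (a, b), d in res.tukey.items()},
            )
        else:
            entry["groups"] = {
                g: {"mean": float(v["value"].mean()), "n": int(len(v))}
                for g, v in sub.groupby("group")
            }
        summary[ep] = entry
        if make_plots:
            _bar_plot(sub, ep, out_dir / f"{safe}.png")
    save_json(summary, out_dir / "summary.json")
    return summary


def _bar_plot(sub: pd.DataFrame, endpoint: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = sub.groupby("group")["value"].agg(["mean", "sem", "count"])
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(agg.index, agg["mean"], yerr=agg["sem"], capsize=4, color="#88aacc")
    ax.set_ylabel(f"{endpoint} ({sub['units'].iloc[0]})")
    ax.set_title(endpoint)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
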