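"""Longitudinal nonparametric statistics for cohort measurement tables.

The measurement table is a tidy :class:`pandas.DataFrame` with columns
``sample_id, group, time_point, roi, measure, value`` — one value per sample,
time point, ROI and measure (e.g. mean T2, contrast).  On it the battery runs

* within-group time effects: Friedman's test over the repeated time points,
  followed by Dunn's post-hoc test on rank sums;
* between-group effects at each time point: Kruskal-Wallis (tie-corrected),
  with Dunn's post-hoc on pooled ranks;
* relative changes Δ_x = (value_tx / value_t0 − 1) × 100 [%] per sample,
  compared between groups with one-way ANOVA and Tukey's HSD.

Normality is deliberately not assumed for the time/group comparisons, while
the Δ comparisons use ANOVA — the battery mirrors common practice in
longitudinal cartilage studies.  Significance is declared at α = 0.01 with no
further correction across the result grid; Dunn post-hoc p-values are
reported unadjusted by default (Holm/Bonferroni configurable).  Ties are
handled by mid-ranks throughout.

Friedman's statistic is computed here (mid-ranks plus the standard tie
correction) rather than delegated, so that a fully tied table degrades
gracefully to statistic 0 / p = 1 instead of a division by zero.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.01
TABLE_COLUMNS = ("sample_id", "group", "time_point", "roi", "measure", "value")


class UndefinedStatisticError(ValueError):
    """A test statistic that cannot be formed from the given data."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test.

    ``posthoc`` maps pair labels to p-values; ``significant`` flags
    ``p_value <= alpha``.  ``defined`` is False when the statistic could not
    be formed (e.g. ANOVA with zero variance everywhere).
    """

    test: str
    statistic: float
    p_value: float
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA
    n: int = 0
    defined: bool = True

    @property
    def significant(self) -> bool:
        return self.defined and self.p_value <= self.alpha

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, p in self.posthoc.items() if p <= self.alpha]


def relative_change(value_tx: float, value_t0: float) -> float:
    """Relative change Δ_x = ((value_tx / value_t0) − 1) × 100, in percent.

    Undefined (raises) when the baseline is not strictly positive.
    """
    if value_t0 <= 0:
        raise UndefinedStatisticError(
            f"relative change undefined for baseline {value_t0} <= 0"
        )
    return (value_tx / value_t0 - 1.0) * 100.0


def _adjust(pvals: list[float], method: str) -> list[float]:
    if method == "none":
        return pvals
    m = len(pvals)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    if method == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        return adj.tolist()
    raise ValueError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# Friedman + Dunn (repeated measures)
# ---------------------------------------------------------------------------

def friedman_statistic(data: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square for an (n blocks × k treatments) array.

    Values are mid-ranked within each block.  The classic statistic is divided
    by the tie-correction factor C = 1 − Σ(t³−t)/(n k (k²−1)); a fully tied
    table (C = 0) returns (0, 1) by convention.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise UndefinedStatisticError("Friedman needs >= 2 blocks and >= 2 treatments")
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    tie_term = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    c = 1.0 - tie_term / (n * k * (k**2 - 1))
    if c <= 0:
        return (0.0, 1.0)
    stat = chi2 / c
    return (float(stat), float(sps.chi2.sf(stat, k - 1)))


def _dunn_repeated(ranks: np.ndarray, labels: list[str], adjust: str) -> dict:
    """Dunn's z-based pairwise procedure on within-block rank sums."""
    n, k = ranks.shape
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    pvals = [float(2.0 * sps.norm.sf(abs(mean_ranks[a] - mean_ranks[b]) / se))
             for a, b in pairs]
    pvals = _adjust(pvals, adjust)
    return {(labels[a], labels[b]): p for (a, b), p in zip(pairs, pvals)}


def friedman_dunn(
    table: pd.DataFrame,
    group: str,
    roi: str,
    measure: str,
    time_points: tuple[str, ...] | None = None,
    adjust: str = "none",
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Friedman test over time points within one group, with Dunn post-hoc.

    Samples missing any time point are excluded with a warning.  Requires at
    least 3 complete samples.
    """
    sub = table[(table["group"] == group) & (table["roi"] == roi)
                & (table["measure"] == measure)]
    wide = sub.pivot(index="sample_id", columns="time_point", values="value")
    if time_points is None:
        time_points = tuple(sorted(wide.columns))
    wide = wide.reindex(columns=list(time_points))
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        warnings.warn(
            f"excluding samples with incomplete time series: {incomplete}",
            stacklevel=2,
        )
        wide = wide.dropna()
    if len(wide) < 3:
        raise UndefinedStatisticError(
            f"Friedman needs >= 3 complete samples; {group}/{roi}/{measure} has {len(wide)}"
        )
    data = wide.to_numpy()
    stat, p = friedman_statistic(data)
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    posthoc = _dunn_repeated(ranks, list(time_points), adjust)
    return TestResult("friedman", stat, p, posthoc, alpha, n=len(wide))


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn (independent groups)
# ---------------------------------------------------------------------------

def _dunn_independent(groups: dict[str, np.ndarray], adjust: str) -> dict:
    """Dunn's pairwise procedure on pooled mid-ranks with tie correction."""
    labels = list(groups)
    values = np.concatenate([groups[g] for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    ranks = sps.rankdata(values)
    mean_ranks, start = {}, 0
    for g in labels:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    n_tot = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_tot - 1))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(labels, 2))
    pvals = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        pvals.append(float(2.0 * sps.norm.sf(abs(z))))
    pvals = _adjust(pvals, adjust)
    return {pair: p for pair, p in zip(pairs, pvals)}


def kruskal_wallis(
    table: pd.DataFrame,
    time_point: str,
    roi: str,
    measure: str,
    adjust: str = "none",
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Kruskal-Wallis H test across groups at one time point, Dunn post-hoc."""
    sub = table[(table["time_point"] == time_point) & (table["roi"] == roi)
                & (table["measure"] == measure)]
    groups = {g: s["value"].to_numpy()
              for g, s in sub.groupby("group", sort=True)}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise UndefinedStatisticError(
            f"Kruskal-Wallis needs >= 2 groups of >= 2 samples at {time_point}"
        )
    samples = list(groups.values())
    if all(np.all(s == samples[0][0]) for s in samples):
        # all observations identical: H = 0 by construction
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*samples)
    posthoc = _dunn_independent(groups, adjust)
    return TestResult("kruskal-wallis", float(stat), float(p), posthoc, alpha,
                      n=sum(len(v) for v in samples))


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD (for relative changes and histology scores)
# ---------------------------------------------------------------------------

def anova_tukey(
    groups: dict[str, np.ndarray],
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """One-way ANOVA with Tukey's HSD pairwise comparisons.

    ``groups`` maps group label to 1D value arrays.  Zero within-group
    variance in every group leaves F undefined; the result is flagged rather
    than raised so report assembly can proceed.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise UndefinedStatisticError("ANOVA needs >= 2 groups with >= 2 values each")
    grand = np.concatenate(arrays)
    ss_within = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    if ss_within == 0.0:
        if all(np.isclose(a.mean(), grand.mean()) for a in arrays):
            # no variance anywhere: F = 0/0
            return TestResult("anova", float("nan"), float("nan"), {}, alpha,
                              n=grand.size, defined=False)
        return TestResult("anova", float("inf"), 0.0, {}, alpha, n=grand.size)
    f_stat, p = sps.f_oneway(*arrays)
    res = sps.tukey_hsd(*arrays)
    posthoc = {
        (labels[a], labels[b]): float(res.pvalue[a, b])
        for a, b in itertools.combinations(range(len(labels)), 2)
    }
    return TestResult("anova", float(f_stat), float(p), posthoc, alpha, n=grand.size)


# ---------------------------------------------------------------------------
# Table assembly, Δ records and the study model
# ---------------------------------------------------------------------------

def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy measurement-table contract and return the frame."""
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
    dup = table.duplicated(subset=["sample_id", "time_point", "roi", "measure"])
    if dup.any():
        raise ValueError(
            "duplicate (sample, time point, roi, measure) rows: "
            f"{table.loc[dup, ['sample_id', 'time_point', 'roi', 'measure']].to_dict('records')[:5]}"
        )
    return table


def delta_table(table: pd.DataFrame, baseline: str = "t0") -> pd.DataFrame:
    """Per-sample relative changes versus baseline, in percent.

    Returns a tidy frame (sample_id, group, roi, measure, delta, value) where
    ``delta`` labels the follow-up time point (e.g. ``t3``).  Samples with a
    non-positive baseline are skipped with a warning.
    """
    rows = []
    skipped = []
    for (sid, grp, roi, measure), sub in table.groupby(
        ["sample_id", "group", "roi", "measure"], sort=True
    ):
        series = sub.set_index("time_point")["value"]
        if baseline not in series.index:
            continue
        v0 = series[baseline]
        if v0 <= 0:
            skipped.append((sid, roi, measure))
            continue
        for tp, v in series.items():
            if tp == baseline:
                continue
            rows.append({
                "sample_id": sid, "group": grp, "roi": roi, "measure": measure,
                "delta": tp, "value": relative_change(v, v0),
            })
    if skipped:
        warnings.warn(f"non-positive baselines skipped: {skipped}", stacklevel=2)
    return pd.DataFrame(rows, columns=["sample_id", "group", "roi", "measure",
                                       "delta", "value"])


class LongitudinalStudy:
    """The full statistical battery over one tidy measurement table.

    Examples
    --------
    >>> study = LongitudinalStudy.from_dataframe(table)
    >>> res = study.fit()
    >>> print(res.summary())
    """

    def __init__(self, table: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                 baseline: str = "t0", adjust: str = "none") -> None:
        self.table = validate_table(table)
        self.alpha = alpha
        self.baseline = baseline
        self.adjust = adjust

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "LongitudinalStudy":
        return cls(table, **kwargs)

    def fit(self) -> "LongitudinalResults":
        t = self.table
        time_points = tuple(sorted(t["time_point"].unique()))
        friedman: dict[tuple, TestResult] = {}
        kruskal: dict[tuple, TestResult] = {}
        anova: dict[tuple, TestResult] = {}

        for (grp, roi, measure), _ in t.groupby(["group", "roi", "measure"], sort=True):
            try:
                friedman[(grp, roi, measure)] = friedman_dunn(
                    t, grp, roi, measure, time_points, self.adjust, self.alpha
                )
            except UndefinedStatisticError:
                pass
        for (tp, roi, measure), _ in t.groupby(["time_point", "roi", "measure"], sort=True):
            try:
                kruskal[(tp, roi, measure)] = kruskal_wallis(
                    t, tp, roi, measure, self.adjust, self.alpha
                )
            except UndefinedStatisticError:
                pass

        deltas = delta_table(t, self.baseline)
        if len(deltas):
            for (dx, roi, measure), sub in deltas.groupby(["delta", "roi", "measure"],
                                                          sort=True):
                groups = {g: s["value"].to_numpy()
                          for g, s in sub.groupby("group", sort=True)}
                if len(groups) >= 2 and all(v.size >= 2 for v in groups.values()):
                    anova[(dx, roi, measure)] = anova_tukey(groups, self.alpha)

        return LongitudinalResults(
            table=t, deltas=deltas, friedman=friedman, kruskal=kruskal,
            anova=anova, alpha=self.alpha, time_points=time_points,
        )


@dataclass
class LongitudinalResults:
    """Fitted battery: per-cell tests plus report builders."""

    table: pd.DataFrame
    deltas: pd.DataFrame
    friedman: dict[tuple, TestResult]
    kruskal: dict[tuple, TestResult]
    anova: dict[tuple, TestResult]
    alpha: float
    time_points: tuple[str, ...]

    # -- report tables ----------------------------------------------------
    def measure_table(self, measure: str) -> pd.DataFrame:
        """Group × time grid of mean ± SD with Friedman column / KW row p's."""
        t = self.table[self.table["measure"] == measure]
        rows = []
        for roi in sorted(t["roi"].unique()):
            for grp in sorted(t[t["roi"] == roi]["group"].unique()):
                row: dict[str, object] = {"roi": roi, "group": grp}
                sub = t[(t["roi"] == roi) & (t["group"] == grp)]
                for tp in self.time_points:
                    vals = sub[sub["time_point"] == tp]["value"].to_numpy()
                    row[tp] = (f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}"
                               if vals.size > 1 else
                               (f"{vals.mean():.1f}" if vals.size else ""))
                fr = self.friedman.get((grp, roi, measure))
                row["friedman_p"] = round(fr.p_value, 4) if fr else np.nan
                row["significant"] = bool(fr and fr.significant)
                rows.append(row)
            kw_row: dict[str, object] = {"roi": roi, "group": "p (between groups)"}
            for tp in self.time_points:
                kw = self.kruskal.get((tp, roi, measure))
                kw_row[tp] = round(kw.p_value, 4) if kw else np.nan
            kw_row["friedman_p"] = np.nan
            kw_row["significant"] = False
            rows.append(kw_row)
        return pd.DataFrame(rows)

    def delta_summary(self, measure: str) -> pd.DataFrame:
        """Group-wise mean ± SD of per-sample Δ_x [%] with ANOVA p row.

        Reports the mean of per-sample relative changes (never the ratio of
        group means) for each follow-up time point.
        """
        d = self.deltas[self.deltas["measure"] == measure]
        deltas = sorted(d["delta"].unique())
        rows = []
        for roi in sorted(d["roi"].unique()):
            for grp in sorted(d[d["roi"] == roi]["group"].unique()):
                row: dict[str, object] = {"roi": roi, "group": grp}
                sub = d[(d["roi"] == roi) & (d["group"] == grp)]
                for dx in deltas:
                    vals = sub[sub["delta"] == dx]["value"].to_numpy()
                    row[dx] = (f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}"
                               if vals.size > 1 else "")
                rows.append(row)
            p_row: dict[str, object] = {"roi": roi, "group": "p (ANOVA)"}
            for dx in deltas:
                res = self.anova.get((dx, roi, measure))
                p_row[dx] = round(res.p_value, 4) if res and res.defined else np.nan
            rows.append(p_row)
        return pd.DataFrame(rows)

    def results_records(self) -> list[dict]:
        """Machine-readable flat list of every test outcome."""
        recs = []
        for (grp, roi, measure), r in self.friedman.items():
            recs.append({"test": r.test, "group": grp, "roi": roi,
                         "measure": measure, "statistic": r.statistic,
                         "p_value": r.p_value, "significant": r.significant,
                         "posthoc": {f"{a}|{b}": p for (a, b), p in r.posthoc.items()}})
        for (tp, roi, measure), r in self.kruskal.items():
            recs.append({"test": r.test, "time_point": tp, "roi": roi,
                         "measure": measure, "statistic": r.statistic,
                         "p_value": r.p_value, "significant": r.significant,
                         "posthoc": {f"{a}|{b}": p for (a, b), p in r.posthoc.items()}})
        for (dx, roi, measure), r in self.anova.items():
            recs.append({"test": r.test, "delta": dx, "roi": roi,
                         "measure": measure, "statistic": r.statistic,
                         "p_value": r.p_value, "significant": r.significant,
                         "posthoc": {f"{a}|{b}": p for (a, b), p in r.posthoc.items()}})
        return recs

    def summary(self) -> str:
        """Human-readable overview of significant findings."""
        lines = [
            "Longitudinal statistics",
            "=======================",
            f"alpha = {self.alpha}; time points: {', '.join(self.time_points)}",
            f"samples: {self.table['sample_id'].nunique()}; "
            f"measures: {', '.join(sorted(self.table['measure'].unique()))}",
            "",
            "significant within-group time effects (Friedman):",
        ]
        sig = [k for k, r in self.friedman.items() if r.significant]
        lines += [f"  {g}/{roi}/{m}: p = {self.friedman[(g, roi, m)].p_value:.2e}"
                  for g, roi, m in sig] or ["  (none)"]
        lines.append("significant between-group effects (Kruskal-Wallis):")
        sig = [k for k, r in self.kruskal.items() if r.significant]
        lines += [f"  {tp}/{roi}/{m}: p = {self.kruskal[(tp, roi, m)].p_value:.2e}"
                  for tp, roi, m in sig] or ["  (none)"]
        lines.append("significant Δ comparisons (ANOVA):")
        sig = [k for k, r in self.anova.items() if r.significant]
        lines += [f"  {dx}/{roi}/{m}: p = {self.anova[(dx, roi, m)].p_value:.2e}"
                  for dx, roi, m in sig] or ["  (none)"]
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        """Write report CSVs (one per measure) and a results JSON."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for measure in sorted(self.table["measure"].unique()):
            self.measure_table(measure).to_csv(
                out / f"summary_{measure}.csv", index=False)
            d = self.delta_summary(measure)
            if len(d):
                d.to_csv(out / f"delta_{measure}.csv", index=False)
        with open(out / "results.json", "w") as fh:
            json.dump(self.results_records(), fh, indent=2)


def report(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
           out_dir=None) -> LongitudinalResults:
    """Run the full battery on a tidy table; optionally write the report."""
    res = LongitudinalStudy(table, alpha=alpha).fit()
    if out_dir is not None:
        res.write(out_dir)
    return res
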