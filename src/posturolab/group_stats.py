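"""Group-comparison statistics and report assembly.

The cohort's tidy metric table is compared between groups with the
nonparametric Mann-Whitney U test (exact null when the combined sample is
small and untied, tie-corrected normal approximation otherwise), after a
single-pass outlier rule: values farther than 1.5 interquartile ranges
from the median are removed per metric per group, with removal counts
reported. Categorical 2x2 contrasts (e.g. multiple-step episodes) are
tested with the chi-squared statistic; because the uncorrected,
Yates-corrected and Fisher exact variants can disagree noticeably at these
sample sizes, all three are reported.

No multiple-testing correction is applied to the headline p-values (the
comparisons are reported as-run); a Benjamini-Hochberg adjusted column is
emitted alongside for transparency.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

TABLE_COLUMNS = ("participant_id", "group", "condition", "metric", "value",
                 "ptype", "discarded", "note")


@dataclass(frozen=True)
class ComparisonResult:
    """One metric's two-group Mann-Whitney comparison."""

    metric_name: str
    n_per_group: tuple
    u: float
    p_two_sided: float
    method: str  # 'exact' | 'asymptotic'
    means_sd: dict  # label -> (mean, sd)
    outliers_removed: dict  # label -> count


@dataclass(frozen=True)
class Assoc2x2Result:
    """Chi-squared / Fisher association tests of a 2x2 count table."""

    table: np.ndarray
    chi2: float
    p_chi2: float
    chi2_yates: float
    p_yates: float
    odds_ratio: float
    p_fisher: float


def remove_outliers(values, k: float = 1.5, min_n: int = 4):
    """Single-pass outlier filter: keep v iff |v - median| <= k * IQR.

    Quartiles use linear interpolation. With fewer than ``min_n`` values
    nothing is removed (a warning is emitted): quartiles of a tiny sample
    are not meaningful. The rule is applied once, not iterated.
    """
    arr = np.asarray(values, dtype=float)
    if len(arr) < min_n:
        warnings.warn(f"outlier rule skipped for n={len(arr)} < {min_n}",
                      stacklevel=2)
        return arr, np.empty(0)
    med = np.median(arr)
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    keep = np.abs(arr - med) <= k * iqr
    return arr[keep], arr[~keep]


def mann_whitney(a, b, metric_name: str = "", exact_max_n: int = 16,
                 labels: tuple = ("a", "b"),
                 outliers_removed: dict | None = None) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two samples.

    Uses the exact null distribution when ``len(a) + len(b) <= exact_max_n``
    and there are no ties, otherwise the tie-corrected normal approximation
    (with continuity correction); the method used is recorded in the
    result. ``u`` is the U statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method=method if method == "exact"
                             else "asymptotic")
    means_sd = {
        labels[0]: (float(np.mean(a)), float(np.std(a, ddof=1)) if len(a) > 1
                    else float("nan")),
        labels[1]: (float(np.mean(b)), float(np.std(b, ddof=1)) if len(b) > 1
                    else float("nan")),
    }
    return ComparisonResult(
        metric_name=metric_name, n_per_group=(len(a), len(b)),
        u=float(res.statistic), p_two_sided=float(res.pvalue), method=method,
        means_sd=means_sd,
        outliers_removed=outliers_removed or {labels[0]: 0, labels[1]: 0})


def categorical_2x2(counts) -> Assoc2x2Result:
    """Association tests of a 2x2 table of non-negative integer counts.

    Reports the uncorrected chi-squared statistic, the Yates-corrected
    variant, and the Fisher exact two-sided p. Raises for a zero margin,
    where expected counts are undefined.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("expected a 2x2 table of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin; association undefined")
    chi2, p_chi2 = stats.chi2_contingency(table, correction=False)[:2]
    chi2_y, p_y = stats.chi2_contingency(table, correction=True)[:2]
    odds, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    return Assoc2x2Result(table=table.astype(int), chi2=float(chi2),
                          p_chi2=float(p_chi2), chi2_yates=float(chi2_y),
                          p_yates=float(p_y), odds_ratio=float(odds),
                          p_fisher=float(p_fisher))


class CohortTable:
    """Tidy per-participant, per-condition metric table.

    One row per (participant, group, condition, metric[, perturbation
    type/index]) with a value and flags; flagged/discarded rows are
    excluded from statistics.
    """

    def __init__(self, rows: list | pd.DataFrame | None = None):
        if isinstance(rows, pd.DataFrame):
            self._rows = rows.to_dict("records")
        else:
            self._rows = list(rows) if rows else []

    def add(self, participant_id: str, group: str, condition: str,
            metric: str, value: float, ptype: str = "", discarded: bool = False,
            note: str = "") -> None:
        self._rows.append(dict(participant_id=participant_id, group=group,
                               condition=condition, metric=metric,
                               value=float(value), ptype=ptype,
                               discarded=bool(discarded), note=note))

    def extend(self, rows) -> None:
        for row in rows:
            self.add(**row)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self._rows, columns=list(TABLE_COLUMNS))
        if len(df):
            df["discarded"] = df["discarded"].astype(bool)
        return df

    def valid(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[~df["discarded"]]

    def __len__(self) -> int:
        return len(self._rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, keep_default_na=False,
                         dtype={"ptype": str, "note": str})
        df["value"] = pd.to_numeric(df["value"])
        df["discarded"] = df["discarded"].astype(str).str.lower().isin(
            ("true", "1"))
        return cls(df)


@dataclass
class CohortReport:
    """Group-comparison report: continuous metrics plus 2x2 step contrast."""

    comparisons: pd.DataFrame
    step_episodes: Assoc2x2Result | None
    step_episode_labels: tuple
    groups: tuple
    discard_rate: float
    per_type: pd.DataFrame | None = None  # per-perturbation-type means

    def to_markdown(self) -> str:
        lines = ["# Cohort group comparison", ""]
        g1, g2 = self.groups
        lines.append(f"Discarded perturbation segments: "
                     f"{100 * self.discard_rate:.1f}%")
        lines.append("")
        df = self.comparisons
        cols = ["metric", "condition", f"mean_sd_{g1}", f"mean_sd_{g2}",
                "n", "outliers_removed", "U", "p", "p_bh", "method"]
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for _, r in df.iterrows():
            lines.append(
                f"| {r['metric']} | {r['condition']} "
                f"| {r[f'mean_{g1}']:.2f} ± {r[f'sd_{g1}']:.2f} "
                f"| {r[f'mean_{g2}']:.2f} ± {r[f'sd_{g2}']:.2f} "
                f"| {int(r[f'n_{g1}'])}/{int(r[f'n_{g2}'])} "
                f"| {int(r[f'outliers_{g1}'])}/{int(r[f'outliers_{g2}'])} "
                f"| {r['U']:.1f} | {r['p']:.4f} | {r['p_bh']:.4f} "
                f"| {r['method']} |")
        if self.per_type is not None and len(self.per_type):
            lines += ["", "## Per-perturbation-type means", ""]
            lines.append(self.per_type.to_string(index=False))
        if self.step_episodes is not None:
            se = self.step_episodes
            lines += ["", "## Multiple-step episodes (single vs multiple)", ""]
            lines.append(f"counts [{g1}, {g2}] x [single, multiple]: "
                         f"{se.table.tolist()}")
            lines.append(f"chi2 = {se.chi2:.4f} (p = {se.p_chi2:.4f}); "
                         f"Yates chi2 = {se.chi2_yates:.4f} "
                         f"(p = {se.p_yates:.4f}); "
                         f"Fisher exact p = {se.p_fisher:.4f}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "groups": list(self.groups),
            "discard_rate": self.discard_rate,
            "comparisons": self.comparisons.to_dict("records"),
        }
        if self.per_type is not None:
            payload["per_type"] = self.per_type.to_dict("records")
        if self.step_episodes is not None:
            se = self.step_episodes
            payload["step_episodes"] = {
                "labels": list(self.step_episode_labels),
                "table": se.table.tolist(),
                "chi2": se.chi2, "p_chi2": se.p_chi2,
                "chi2_yates": se.chi2_yates, "p_yates": se.p_yates,
                "odds_ratio": se.odds_ratio, "p_fisher": se.p_fisher,
            }
        return json.dumps(payload, indent=2)


def _participant_means(df: pd.DataFrame) -> pd.DataFrame:
    """Average repeated (e.g. per-perturbation) values per participant."""
    return (df.groupby(["participant_id", "group", "condition", "metric"],
                       as_index=False)["value"].mean())


def build_report(table: CohortTable, groups: tuple = ("control", "PD"),
                 outlier_k: float = 1.5, exact_max_n: int = 16,
                 pooled_step_table: bool = True) -> CohortReport:
    """Assemble the per-metric group comparison report.

    Per (metric, condition): repeated rows are averaged per participant,
    the single-pass IQR outlier rule is applied per group, and groups are
    compared with Mann-Whitney. The multiple-step 2x2 contrast pools step
    episodes (single vs multiple) over participants per group.
    """
    df = table.to_frame()
    discard_rate = float(df["discarded"].mean()) if len(df) else 0.0
    valid = df[~df["discarded"]]
    per_part = _participant_means(valid[~valid["metric"].isin(["n_steps"])])

    rows = []
    g1, g2 = groups
    for (metric, condition), sub in per_part.groupby(["metric", "condition"],
                                                     sort=True):
        vals = {g: sub.loc[sub["group"] == g, "value"].to_numpy()
                for g in groups}
        kept, removed = {}, {}
        for g in groups:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept[g], removed[g] = remove_outliers(vals[g], k=outlier_k)
        row = dict(metric=metric, condition=condition)
        for g in groups:
            row[f"n_{g}"] = len(kept[g])
            row[f"outliers_{g}"] = len(removed[g])
            row[f"mean_{g}"] = float(np.mean(kept[g])) if len(kept[g]) \
                else float("nan")
            row[f"sd_{g}"] = float(np.std(kept[g], ddof=1)) \
                if len(kept[g]) > 1 else float("nan")
        if len(kept[g1]) >= 3 and len(kept[g2]) >= 3:
            cmp_res = mann_whitney(kept[g1], kept[g2], metric_name=metric,
                                   exact_max_n=exact_max_n, labels=groups)
            row.update(U=cmp_res.u, p=cmp_res.p_two_sided,
                       method=cmp_res.method)
        else:
            row.update(U=float("nan"), p=float("nan"), method="n/a")
            warnings.warn(f"metric {metric}/{condition}: too few values for "
                          "a group comparison", stacklevel=2)
        rows.append(row)
    comparisons = pd.DataFrame(rows)
    if len(comparisons):
        mask = comparisons["p"].notna()
        p_bh = np.full(len(comparisons), np.nan)
        if mask.any():
            p_bh[mask.to_numpy()] = stats.false_discovery_control(
                comparisons.loc[mask, "p"].to_numpy())
        comparisons["p_bh"] = p_bh

    # per-perturbation-type means of the dynamic metrics (pooled rows carry
    # the grouped comparison; types are emitted descriptively)
    typed = valid[(valid["ptype"] != "") & (~valid["metric"].isin(
        ["n_steps", "step_response"]))]
    per_type = None
    if len(typed):
        per_type = (typed.groupby(["metric", "ptype", "group"])["value"]
                    .agg(["mean", "std", "count"]).reset_index())
    step_res = None
    labels = ("single_step", "multiple_steps")
    steps = valid[valid["metric"] == "n_steps"]
    if len(steps) and pooled_step_table:
        counts = np.zeros((2, 2), dtype=int)
        for gi, g in enumerate(groups):
            nsteps = steps.loc[steps["group"] == g, "value"].to_numpy()
            counts[gi, 0] = int(np.sum(nsteps == 1))
            counts[gi, 1] = int(np.sum(nsteps >= 2))
        if counts.sum(axis=0).min() > 0 and counts.sum(axis=1).min() > 0:
            step_res = categorical_2x2(counts)
    return CohortReport(comparisons=comparisons, step_episodes=step_res,
                        step_episode_labels=labels, groups=groups,
                        discard_rate=discard_rate, per_type=per_type)


def write_report(report: CohortReport, out_dir) -> None:
    """Write the report in CSV, JSON and markdown forms."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.comparisons.to_csv(out / "report.csv", index=False)
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(report.to_markdown())
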