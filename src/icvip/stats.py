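"""Study-level statistics and report assembly.

Group contrasts use the Wilcoxon rank-sum test (exact for small samples
without ties, normal approximation with tie correction otherwise) or a
two-tailed t-test; proportions are reported at the table's printed
precision; ``build_report`` merges the per-neuron tables and recomputes
every summary from the merged table so no report number carries hidden
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientDataError


@dataclass
class ProportionReport:
    label: str
    numerator: int
    denominator: int
    percent: float            # rounded to the requested precision

    def __str__(self) -> str:
        return f"{self.label}: {self.percent:g}% ({self.numerator} of {self.denominator})"


@dataclass
class GroupContrast:
    metric: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str                 # wilcoxon_rank_sum | t_two_tailed
    statistic: float
    p_value: float


def proportion(numerator: int, denominator: int, label: str = "",
               decimals: int = 1) -> ProportionReport:
    """Percentage ``100*num/den`` rounded to ``decimals`` (one decimal for
    physiology tables, integer for morphology counts)."""
    if denominator <= 0:
        raise ConfigurationError("denominator must be > 0")
    if numerator < 0 or numerator > denominator:
        raise ConfigurationError("need 0 <= numerator <= denominator")
    pct = round(100.0 * numerator / denominator, decimals)
    if decimals == 0:
        pct = float(int(pct))
    return ProportionReport(label=label, numerator=int(numerator),
                            denominator=int(denominator), percent=pct)


def rank_sum_test(a: Sequence[float], b: Sequence[float],
                  max_exact_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples are small and tie-free,
    otherwise the normal approximation with continuity and tie correction.
    Returns (rank-sum statistic W of sample a, p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need n >= 2 per group")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:a.size].sum())
    if np.ptp(pooled) == 0:
        return w, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = ("exact" if (max(a.size, b.size) <= max_exact_n and not has_ties)
              else "asymptotic")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return w, float(res.pvalue)


def group_compare(a: Sequence[float], b: Sequence[float],
                  test: str = "wilcoxon_rank_sum",
                  metric: str = "", group_a: str = "a", group_b: str = "b",
                  ) -> GroupContrast:
    """Two-group contrast with descriptive mean +/- SD per group."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need n >= 2 per group")
    if test == "wilcoxon_rank_sum":
        stat, p = rank_sum_test(a, b)
    elif test == "t_two_tailed":
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            res = sps.ttest_ind(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ConfigurationError(f"unknown test {test!r}")
    return GroupContrast(
        metric=metric, group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        test=test, statistic=float(stat), p_value=float(p))


@dataclass
class ReportBundle:
    merged: Optional[pd.DataFrame]
    summaries: dict = field(default_factory=dict)
    proportions: list = field(default_factory=list)
    notices: list = field(default_factory=list)

    def summary_text(self) -> str:
        lines = []
        for p in self.proportions:
            lines.append(str(p))
        for name, df in self.summaries.items():
            lines.append(f"\n== {name} ==")
            lines.append(df.to_string())
        for n in self.notices:
            lines.append(f"[notice] {n}")
        return "\n".join(lines)


def _check_unique_ids(df: pd.DataFrame, name: str) -> None:
    if "neuron_id" in df.columns and df["neuron_id"].duplicated().any():
        dups = sorted(df.loc[df["neuron_id"].duplicated(), "neuron_id"].unique())
        raise ConfigurationError(f"duplicate neuron ids in {name}: {dups}")


def build_report(profiles: Optional[pd.DataFrame] = None,
                 morphometrics: Optional[pd.DataFrame] = None,
                 stereo_estimates: Optional[pd.DataFrame] = None,
                 plane_fits: Optional[pd.DataFrame] = None,
                 psp_tables: Optional[pd.DataFrame] = None) -> ReportBundle:
    """Merge per-neuron tables and recompute all summary statistics.

    At least one table is required; missing sections are omitted with a
    notice.  Neuron-level tables (intrinsic profiles, morphometrics) join on
    ``neuron_id``.
    """
    inputs = {"profiles": profiles, "morphometrics": morphometrics,
              "stereology": stereo_estimates, "plane_fits": plane_fits,
              "psp": psp_tables}
    if all(v is None for v in inputs.values()):
        raise InsufficientDataError("no input tables")
    bundle = ReportBundle(merged=None)

    merged = None
    for name in ("profiles", "morphometrics"):
        df = inputs[name]
        if df is None or df.empty:
            bundle.notices.append(f"{name} table absent; section omitted")
            continue
        _check_unique_ids(df, name)
        merged = df if merged is None else merged.merge(
            df, on="neuron_id", how="outer", suffixes=("", f"_{name}"))
    bundle.merged = merged

    if merged is not None and "firing_class" in merged.columns:
        counts = merged["firing_class"].value_counts()
        total = int(counts.sum())
        bundle.summaries["firing_class_proportions"] = pd.DataFrame({
            "count": counts,
            "percent": [proportion(int(c), total, decimals=1).percent
                        for c in counts]})
        for cls, c in counts.items():
            bundle.proportions.append(
                proportion(int(c), total, label=f"{cls} firing", decimals=1))
    if merged is not None and "shape_class" in merged.columns:
        counts = merged["shape_class"].dropna().value_counts()
        total = int(counts.sum())
        if total:
            bundle.summaries["shape_class_proportions"] = pd.DataFrame({
                "count": counts,
                "percent": [proportion(int(c), total, decimals=0).percent
                            for c in counts]})
            for cls, c in counts.items():
                bundle.proportions.append(
                    proportion(int(c), total, label=f"{cls} morphology",
                               decimals=0))
    if merged is not None:
        numeric = merged.select_dtypes("number")
        if not numeric.empty:
            bundle.summaries["intrinsic_summary"] = numeric.agg(
                ["mean", "std", "count"]).T
    for name in ("stereology", "plane_fits", "psp"):
        df = inputs[name]
        if df is None or (hasattr(df, "empty") and df.empty):
            bundle.notices.append(f"{name} table absent; section omitted")
        else:
            bundle.summaries[name] = df
    return bundle
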