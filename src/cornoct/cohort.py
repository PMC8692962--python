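"""Paired pre/post cohort statistics for orthokeratology studies.

Each subject contributes one eye measured before and after lens wear.
Zone-level thickness means and central radii are compared with two-sided
paired t-tests; normality is screened with a Kolmogorov-Smirnov test
against a normal with the sample's own mean and SD (advisory only — the
t-test is run regardless, as is conventional in this literature).
Percent change is the mean of per-subject percent changes, not the
percent change of the means.  Pointwise thickness-change profiles carry
an uncorrected p-value per lateral position.

The model-style entry point is :class:`PairedCohort` -> ``fit()`` ->
:class:`PairedCohortResult` with Table-1/2/3-shaped summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiling import ThicknessProfile

__all__ = [
    "CohortTable",
    "PairedResult",
    "ks_normality",
    "paired_t",
    "pointwise_change_profile",
    "summary_tables",
    "PairedCohort",
    "PairedCohortResult",
    "format_p",
]

ALPHA = 0.05
REQUIRED_COLUMNS = ["subject", "visit", "kind", "name", "meridian", "zone", "value"]


class DegenerateSampleError(ValueError):
    pass


@dataclass(frozen=True)
class PairedResult:
    """Paired t-test outcome for one measure."""

    measure: str
    n: int
    mean_pre: float
    mean_post: float
    mean_change: float
    sd_change: float
    t_stat: float
    p_value: float
    percent_change: float  # mean of per-subject percent changes

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class CohortTable:
    """Tidy per-subject measurement table.

    Columns: subject, visit (pre|post), kind (thickness|radius), name
    (layer or surface), meridian (horizontal|vertical|both), zone
    (central|paracentral, empty for radii), value (um for thickness, mm
    for radii).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(REQUIRED_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("cohort table is empty")
        bad = set(df["visit"].unique()) - {"pre", "post"}
        if bad:
            raise ValueError(f"visit must be pre|post, found {sorted(bad)}")
        keys = df[["subject", "visit", "kind", "name", "meridian", "zone"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].to_dict()
            raise ValueError(f"duplicated (subject, visit, measure) row: {dup}")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, keep_default_na=False))

    def measures(self) -> pd.DataFrame:
        return self.data[["kind", "name", "meridian", "zone"]].drop_duplicates()


def ks_normality(values) -> tuple[float, bool]:
    """One-sample KS test against N(sample mean, sample SD).

    Returns ``(p_value, non_normal_flag)``; the flag is raised at p < 0.05.
    Advisory — downstream paired t-tests run regardless of the flag.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValueError(f"normality screen needs n >= 5, got {len(v)}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero-variance sample: normality test undefined")
    p = float(stats.kstest(v, "norm", args=(v.mean(), sd)).pvalue)
    return p, p < ALPHA


def paired_t(pre, post, measure: str = "") -> PairedResult:
    """Two-sided paired t-test of post vs pre, matched by position.

    The all-zero-difference case (post identical to pre) is reported as
    t = 0, p = 1; identical *nonzero* differences (zero SD, nonzero mean)
    are degenerate and raise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"pre/post lengths differ: {pre.shape} vs {post.shape}")
    n = len(pre)
    if n < 2:
        raise ValueError(f"paired test needs n >= 2, got {n}")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            t_stat, p = 0.0, 1.0
        else:
            raise DegenerateSampleError(
                f"{measure or 'measure'}: all paired differences identical "
                f"({diff[0]:+.3g}) — t statistic undefined"
            )
    else:
        res = stats.ttest_rel(post, pre)
        t_stat, p = float(res.statistic), float(res.pvalue)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(pre != 0, diff / pre * 100.0, np.nan)
    return PairedResult(
        measure=measure,
        n=n,
        mean_pre=float(pre.mean()),
        mean_post=float(post.mean()),
        mean_change=float(diff.mean()),
        sd_change=float(sd),
        t_stat=t_stat,
        p_value=p,
        percent_change=float(np.nanmean(pct)) if np.any(pre != 0) else float("nan"),
    )


def pointwise_change_profile(
    pre_profiles: dict[str, ThicknessProfile],
    post_profiles: dict[str, ThicknessProfile],
) -> pd.DataFrame:
    """Per-x mean thickness change and paired-t p-value across subjects.

    Profiles must share the Z-line grid; at each x, subjects enter the test
    only when both visits cover that position.  Positions with fewer than
    two complete pairs are reported with NaN change and p (missing, not
    fabricated).  No multiple-testing correction is applied.
    """
    subjects = sorted(set(pre_profiles) & set(post_profiles))
    if not subjects:
        raise ValueError("no subjects present in both pre and post cohorts")
    xs = np.unique(np.concatenate([pre_profiles[s].x_mm for s in subjects]))
    rows = []
    for x in xs:
        pre_v, post_v = [], []
        for s in subjects:
            p, q = pre_profiles[s], post_profiles[s]
            i = np.flatnonzero(p.x_mm == x)
            j = np.flatnonzero(q.x_mm == x)
            if len(i) and len(j):
                pre_v.append(p.thickness_um[i[0]])
                post_v.append(q.thickness_um[j[0]])
        if len(pre_v) < 2:
            rows.append((x, np.nan, np.nan, len(pre_v)))
            continue
        try:
            r = paired_t(pre_v, post_v, measure=f"x={x:.3f}")
            rows.append((x, r.mean_change, r.p_value, r.n))
        except DegenerateSampleError:
            # identical nonzero differences: t-test limit is p -> 0
            d = np.asarray(post_v) - np.asarray(pre_v)
            rows.append((x, float(d.mean()), 0.0, len(pre_v)))
    return pd.DataFrame(rows, columns=["x_mm", "mean_change_um", "p_value", "n"])


def format_p(p: float) -> str:
    """Clinical-table p formatting: values below 0.01 print as '<0.01'."""
    if np.isnan(p):
        return "nan"
    return "<0.01" if p < 0.01 else f"{p:.3f}"


def _paired_frame(df: pd.DataFrame, measure: str) -> PairedResult | None:
    """Paired result for one measure subframe, dropping unpaired subjects."""
    wide = df.pivot(index="subject", columns="visit", values="value")
    if "pre" not in wide or "post" not in wide:
        return None
    unpaired = wide.index[wide.isna().any(axis=1)]
    if len(unpaired):
        warnings.warn(
            f"{measure}: excluding unpaired subject(s) {sorted(unpaired)}", stacklevel=2
        )
        wide = wide.dropna()
    if len(wide) < 2:
        return None
    pre = wide["pre"].to_numpy()
    post = wide["post"].to_numpy()
    try:
        return paired_t(pre, post, measure=measure)
    except DegenerateSampleError:
        # identical nonzero differences: the limit of the t-test is p -> 0
        warnings.warn(f"{measure}: zero-variance differences, reporting p=0", stacklevel=2)
        diff = post - pre
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(pre != 0, diff / pre * 100.0, np.nan)
        return PairedResult(
            measure=measure,
            n=len(pre),
            mean_pre=float(pre.mean()),
            mean_post=float(post.mean()),
            mean_change=float(diff.mean()),
            sd_change=0.0,
            t_stat=float(np.inf * np.sign(diff.mean())),
            p_value=0.0,
            percent_change=float(np.nanmean(pct)) if np.any(pre != 0) else float("nan"),
        )


def summary_tables(cohort: CohortTable) -> dict[str, pd.DataFrame]:
    """Clinical-style zone and radius tables with paired p-values.

    Returns three frames: ``central`` (thickness, meridians pooled),
    ``paracentral`` (thickness per meridian), ``radii`` (central radius per
    surface per meridian).  Each row reports mean +/- SD before and after
    plus the paired p-value, with sub-0.01 p printed as '<0.01'.
    """
    df = cohort.data
    out: dict[str, pd.DataFrame] = {}

    def _rows(sub: pd.DataFrame, group_cols: list[str], unit: str):
        recs = []
        for key, g in sub.groupby(group_cols, sort=False):
            key = key if isinstance(key, tuple) else (key,)
            label = "/".join(str(k) for k in key)
            r = _paired_frame(g, label)
            if r is None:
                warnings.warn(f"{label}: no complete pairs, skipped", stacklevel=3)
                continue
            pre_sd = g[g.visit == "pre"]["value"].std(ddof=1)
            post_sd = g[g.visit == "post"]["value"].std(ddof=1)
            recs.append(
                dict(zip(group_cols, key))
                | {
                    "n": r.n,
                    f"before_mean_{unit}": round(r.mean_pre, 2),
                    f"before_sd_{unit}": round(float(pre_sd), 2),
                    f"after_mean_{unit}": round(r.mean_post, 2),
                    f"after_sd_{unit}": round(float(post_sd), 2),
                    "p_value": r.p_value,
                    "p_display": format_p(r.p_value),
                }
            )
        return pd.DataFrame(recs)

    thick = df[df.kind == "thickness"]
    central = thick[(thick.zone == "central") & (thick.meridian == "both")]
    if len(central):
        out["central"] = _rows(central, ["name"], "um")
    para = thick[(thick.zone == "paracentral") & (thick.meridian != "both")]
    if len(para):
        out["paracentral"] = _rows(para, ["name", "meridian"], "um")
    radii = df[df.kind == "radius"]
    if len(radii):
        out["radii"] = _rows(radii, ["name", "meridian"], "mm")
    if not out:
        raise ValueError("cohort table contains no summarisable measures")
    return out


class PairedCohort:
    """Paired pre/post cohort model over a :class:`CohortTable`.

    ``fit()`` screens every measure for normality, runs the paired t-tests
    and assembles the clinical summary tables.
    """

    def __init__(self, table: CohortTable | pd.DataFrame) -> None:
        self.table = table if isinstance(table, CohortTable) else CohortTable(table)

    def fit(self) -> "PairedCohortResult":
        results: dict[str, PairedResult] = {}
        normality: dict[str, tuple[float, bool]] = {}
        df = self.table.data
        for key, g in df.groupby(["kind", "name", "meridian", "zone"], sort=False):
            label = "/".join(str(k) for k in key if k != "")
            r = _paired_frame(g, label)
            if r is None:
                continue
            results[label] = r
            wide = g.pivot(index="subject", columns="visit", values="value").dropna()
            diffs = (wide["post"] - wide["pre"]).to_numpy()
            try:
                normality[label] = ks_normality(diffs)
            except (ValueError, DegenerateSampleError):
                normality[label] = (float("nan"), False)
        tables = summary_tables(self.table)
        return PairedCohortResult(results=results, normality=normality, tables=tables)


@dataclass
class PairedCohortResult:
    """Fitted cohort comparison: per-measure paired results and tables."""

    results: dict[str, PairedResult]
    normality: dict[str, tuple[float, bool]]
    tables: dict[str, pd.DataFrame]

    def __getitem__(self, measure: str) -> PairedResult:
        return self.results[measure]

    def summary(self) -> str:
        lines = ["Paired pre/post cohort comparison", "=" * 78]
        hdr = (
            f"{'measure':<38}{'n':>4}{'pre':>9}{'post':>9}{'change':>9}"
            f"{'%chg':>7}{'p':>8}"
        )
        lines.append(hdr)
        lines.append("-" * 78)
        for label, r in self.results.items():
            flag = " *" if self.normality.get(label, (1.0, False))[1] else ""
            lines.append(
                f"{label:<38}{r.n:>4}{r.mean_pre:>9.2f}{r.mean_post:>9.2f}"
                f"{r.mean_change:>+9.2f}{r.percent_change:>7.1f}{format_p(r.p_value):>8}{flag}"
            )
        lines.append("-" * 78)
        lines.append("* KS normality flag raised on the paired differences (advisory)")
        return "\n".join(lines)
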