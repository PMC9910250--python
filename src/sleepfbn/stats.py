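"""Endpoint statistics: the trial's comparison plan on metric, scale and volume tables.

Test selection follows the common clinical convention behind "as appropriate":
a Shapiro–Wilk normality gate at α = 0.05 on each group (on the difference
vector for paired designs) chooses between the parametric test (Student's t,
paired t, repeated-measures ANOVA) and its rank-based counterpart
(Mann–Whitney U, Wilcoxon signed-rank).  Descriptives are reported as
mean ± SD when the parametric branch is taken and median (Q1–Q3) otherwise.
All tests are two-tailed at α = 0.05; no multiple-testing correction is
applied across scales or regions (the number of contrasts is reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
    PairingError,
)

logger = logging.getLogger(__name__)

ALPHA = 0.05
NORMALITY_ALPHA = 0.05


@dataclass
class ComparisonResult:
    """One statistical contrast: the design, the test chosen, and its result."""

    design: str               # independent | paired | longitudinal | categorical
    test_used: str
    statistic: float
    p_value: float
    descriptives: list = field(default_factory=list)  # one dict per group
    n: tuple = ()
    alpha: float = ALPHA
    two_tailed: bool = True
    normal: bool | None = None
    notes: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise InvalidInputError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def summary(self) -> str:
        groups = "; ".join(d.get("summary", "") for d in self.descriptives)
        return (
            f"{self.design}: {self.test_used}, statistic={self.statistic:.4g}, "
            f"p={self.p_value:.4g} ({groups})"
        )


def _describe(x: np.ndarray, normal: bool, label: str = "") -> dict:
    """Group descriptives in the style matching the normality verdict."""
    x = np.asarray(x, dtype=float)
    d = {
        "label": label,
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "median": float(np.median(x)),
        "q1": float(np.percentile(x, 25)),
        "q3": float(np.percentile(x, 75)),
    }
    if normal:
        d["summary"] = f"{d['mean']:.2f} ± {d['sd']:.2f}"
    else:
        d["summary"] = f"{d['median']:.2f} ({d['q1']:.2f}–{d['q3']:.2f})"
    return d


def _is_normal(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    """Shapiro–Wilk gate; constant vectors fail, n < 3 passes by convention."""
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        return False
    if x.size < 3:
        return True  # unassessable at n = 2; parametric is the convention
    return bool(sstats.shapiro(x).pvalue >= alpha)


def compare_independent(values_a, values_b, labels=("a", "b")) -> ComparisonResult:
    """Between-group contrast: Student's t (pooled variance) or Mann–Whitney U.

    The parametric branch is taken only when both groups pass the normality
    gate.  Raises :class:`DegenerateDataError` when both groups are constant
    with equal means (no test is defined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(f"need n >= 2 per group, got {a.size} and {b.size}")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        raise DegenerateDataError("both groups constant with equal means")
    normal = _is_normal(a) and _is_normal(b)
    if normal:
        res = sstats.ttest_ind(a, b, equal_var=True)
        test = "Student's t (independent, pooled variance)"
    else:
        res = sstats.mannwhitneyu(a, b, alternative="two-sided")
        test = "Mann–Whitney U"
    logger.debug("independent contrast: normality=%s -> %s", normal, test)
    return ComparisonResult(
        design="independent",
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        descriptives=[_describe(a, normal, labels[0]), _describe(b, normal, labels[1])],
        n=(a.size, b.size),
        normal=normal,
    )


def compare_paired(before, after, labels=("before", "after")) -> ComparisonResult:
    """Paired contrast: paired Student's t or Wilcoxon signed-rank on differences."""
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError(f"paired vectors differ in length: {x.size} vs {y.size}")
    if x.size < 2:
        raise InsufficientDataError(f"need n >= 2 pairs, got {x.size}")
    diff = y - x
    if np.all(diff == 0):
        raise DegenerateDataError("all paired differences are exactly zero")
    if np.std(diff) == 0:
        raise DegenerateDataError(
            "paired differences are constant (zero variance): paired t undefined"
        )
    normal = _is_normal(diff)
    if normal:
        res = sstats.ttest_rel(y, x)
        test = "Student's t (paired)"
    else:
        res = sstats.wilcoxon(y, x)
        test = "Wilcoxon signed-rank"
    logger.debug("paired contrast: normality=%s -> %s", normal, test)
    return ComparisonResult(
        design="paired",
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        descriptives=[_describe(x, normal, labels[0]), _describe(y, normal, labels[1])],
        n=(x.size,),
        normal=normal,
    )


def compare_longitudinal(
    table: pd.DataFrame,
    measure: str | None = None,
    correction: str = "auto",
    subject_col: str = "subject_id",
    time_col: str = "timepoint",
    value_col: str = "value",
) -> ComparisonResult:
    """One-way repeated-measures ANOVA across timepoints.

    Missing data are handled complete-case: subjects lacking any timepoint
    are dropped.  Sphericity handling follows the usual SPSS-style workflow:
    with ``correction="auto"`` the Greenhouse–Geisser-corrected p-value is
    used when Mauchly's test rejects sphericity, otherwise the uncorrected
    one; ``"always"`` / ``"never"`` force one branch.  With two timepoints
    the design reduces to the paired t test (F = t²).
    """
    import pingouin as pg

    df = table
    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
    df = df[[subject_col, time_col, value_col]].dropna()
    if df.empty:
        raise InsufficientDataError("no usable rows for longitudinal contrast")
    timepoints = list(pd.unique(df[time_col]))
    if len(timepoints) < 2:
        raise InsufficientDataError("need at least 2 timepoints")
    counts = df.groupby(subject_col)[time_col].nunique()
    complete = counts[counts == len(timepoints)].index
    dropped = counts.index.difference(complete)
    if len(dropped) > 0:
        logger.info("complete-case analysis drops %d subject(s): %s",
                    len(dropped), ", ".join(map(str, dropped)))
    df = df[df[subject_col].isin(complete)]
    n_subjects = df[subject_col].nunique()
    if n_subjects < 3:
        raise InsufficientDataError(
            f"need >= 3 subjects with complete data, got {n_subjects}"
        )
    aov = pg.rm_anova(
        data=df, dv=value_col, within=time_col, subject=subject_col,
        correction=True, detailed=False,
    )
    row = aov.iloc[0]

    def _col(*names, default=None):
        for name in names:
            if name in aov.columns and pd.notna(row[name]):
                return row[name]
        return default

    p_unc = float(_col("p_unc", "p-unc"))
    p_gg_raw = _col("p_GG_corr", "p-GG-corr")
    p_gg = float(p_gg_raw) if p_gg_raw is not None else p_unc
    spher_ok = bool(_col("sphericity", default=True))
    if len(timepoints) == 2:
        p, note = p_unc, "two timepoints: equivalent to paired t (F = t²)"
    elif correction == "always":
        p, note = p_gg, "Greenhouse–Geisser corrected"
    elif correction == "never":
        p, note = p_unc, "sphericity assumed"
    elif correction == "auto":
        if spher_ok:
            p, note = p_unc, "sphericity not rejected (Mauchly): uncorrected p"
        else:
            p, note = p_gg, "sphericity rejected (Mauchly): Greenhouse–Geisser corrected"
    else:
        raise InvalidInputError(f"unknown correction policy {correction!r}")
    desc = [
        _describe(df.loc[df[time_col] == tp, value_col].to_numpy(), True, str(tp))
        for tp in timepoints
    ]
    return ComparisonResult(
        design="longitudinal",
        test_used="one-way repeated-measures ANOVA",
        statistic=float(row["F"]),
        p_value=p,
        descriptives=desc,
        n=(n_subjects,),
        normal=None,
        notes=note,
    )


def compare_categorical(counts) -> ComparisonResult:
    """χ² test of homogeneity on a 2 x k count table.

    Fisher's exact test is substituted (and logged) when any expected cell
    count falls below 5 in a 2 x 2 table; for larger tables with sparse cells
    the χ² result is kept with a logged caveat.  Raises
    :class:`InvalidInputError` on empty tables or zero marginal totals.
    """
    t = np.asarray(counts)
    if t.size == 0 or t.ndim != 2:
        raise InvalidInputError("counts must be a non-empty 2-D table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.number):
        raise InvalidInputError("counts must be nonnegative numbers")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise InvalidInputError("count table has a zero row or column total")
    chi2, p, dof, expected = sstats.chi2_contingency(t, correction=False)
    test = "chi-squared"
    stat = float(chi2)
    if (expected < 5).any():
        if t.shape == (2, 2):
            stat, p = sstats.fisher_exact(t)
            test = "Fisher's exact"
            logger.info("expected cell < 5: substituting Fisher's exact test")
        else:
            logger.warning("expected cell < 5 in a 2x%d table: chi-squared kept", t.shape[1])
    return ComparisonResult(
        design="categorical",
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        descriptives=[],
        n=tuple(int(v) for v in t.sum(axis=1)),
        normal=None,
    )


def percent_change(baseline_mean: float, followup_mean: float) -> float:
    """Percent change 100·(follow-up − baseline)/baseline, to 2 decimals."""
    if baseline_mean <= 0:
        raise InvalidInputError(f"baseline mean must be positive, got {baseline_mean}")
    return round(100.0 * (followup_mean - baseline_mean) / baseline_mean, 2)


def volume_region_analysis(table: pd.DataFrame, timepoints=("baseline", "6M")):
    """Paired baseline-vs-follow-up analysis of a regional volume table.

    For every region (including the ``TOTAL`` pseudo-region): a paired
    contrast of the two timepoints, the mean of per-subject percent changes,
    and the percent change of the group means (the convention used for
    whole-gray-matter change).

    Returns ``(summary, results)`` where ``summary`` is a DataFrame with one
    row per region and ``results`` maps region -> :class:`ComparisonResult`.

    Raises :class:`PairingError` naming any subject missing a timepoint.
    """
    t0, t1 = timepoints
    for col in ("subject_id", "region", "timepoint", "volume"):
        if col not in table.columns:
            raise InvalidInputError(f"volume table lacks column {col!r}")
    if (table["volume"] <= 0).any():
        raise InvalidInputError("volumes must be positive")
    rows, results = [], {}
    for region, sub in table.groupby("region", sort=False):
        wide = sub.pivot_table(index="subject_id", columns="timepoint", values="volume")
        for tp in timepoints:
            if tp not in wide.columns:
                raise PairingError(f"region {region!r} lacks timepoint {tp!r}")
            missing = wide.index[wide[tp].isna()]
            if len(missing) > 0:
                raise PairingError(
                    f"subject(s) {', '.join(map(str, missing))} unpaired in region {region!r}"
                )
        v0 = wide[t0].to_numpy()
        v1 = wide[t1].to_numpy()
        res = compare_paired(v0, v1, labels=timepoints)
        results[region] = res
        idx = sub["region_index"].iloc[0] if "region_index" in sub.columns else np.nan
        rows.append({
            "region_index": idx,
            "region": region,
            "n": len(wide),
            f"{t0}_mean": round(float(v0.mean()), 2),
            f"{t0}_sd": round(float(np.std(v0, ddof=1)), 2),
            f"{t1}_mean": round(float(v1.mean()), 2),
            f"{t1}_sd": round(float(np.std(v1, ddof=1)), 2),
            "test_used": res.test_used,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "mean_percent_change": round(float(np.mean(100.0 * (v1 - v0) / v0)), 2),
            "percent_change_of_means": percent_change(float(v0.mean()), float(v1.mean())),
        })
    logger.info("volume analysis performed %d paired contrasts (no multiplicity correction)",
                len(rows))
    return pd.DataFrame(rows), results
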