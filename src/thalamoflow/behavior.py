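"""Behavioral and model-comparison statistics.

One-way repeated-measures ANOVA (F = MS_condition / MS_(condition x
subject)), paired t-tests with Bonferroni correction, and Cohen's d with
the two conditions' pooled across-subject SD. A reader for the study-style
source-data workbook (one column block per condition) turns sheets into
tidy subject x condition tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError


@dataclass
class StatResult:
    """One test statistic with its df, p and effect size."""

    name: str                    # "F" or "t"
    value: float
    df: tuple[int, ...] | int
    p: float
    effect_size: float
    effect_size_name: str
    correction: str = "none"
    comparison: str = ""

    def __str__(self) -> str:
        df = ",".join(str(d) for d in (self.df if isinstance(self.df, tuple) else (self.df,)))
        return (f"{self.comparison + ': ' if self.comparison else ''}"
                f"{self.name}({df}) = {self.value:.2f}, p = {self.p:.4g}, "
                f"{self.effect_size_name} = {self.effect_size:.2f}"
                f"{' (' + self.correction + ')' if self.correction != 'none' else ''}")


def _pivot(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    required = {"subject", "condition", value}
    if not required <= set(table.columns):
        raise ValidationError(f"table needs columns {sorted(required)}")
    wide = table.pivot(index="subject", columns="condition", values=value)
    if wide.isna().any().any():
        raise ValidationError("incomplete subject x condition crossing")
    return wide


def rm_anova_oneway(table: pd.DataFrame, value: str = "value") -> StatResult:
    """One-way repeated-measures ANOVA on a tidy subject x condition table.

    F = MS_condition / MS_(condition x subject), df = (k-1, (k-1)(n-1)).
    The effect size is generalized eta squared (eta2_G), which for this
    design is SS_condition / (SS_condition + SS_subject + SS_error).
    """
    wide = _pivot(table, value)
    n, k = wide.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 conditions")
    X = wide.to_numpy(float)
    grand = X.mean()
    ss_cond = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ss_cond == 0 else np.inf)
    p = float(stats.f.sf(F, df_cond, df_err)) if np.isfinite(F) else 0.0
    denom = ss_cond + ss_subj + ss_err
    ges = float(ss_cond / denom) if denom > 0 else 0.0
    return StatResult(
        name="F", value=float(F), df=(df_cond, df_err), p=p,
        effect_size=ges, effect_size_name="eta2_G",
    )


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled SD of the two conditions.

    d = (mean_x - mean_y) / sqrt((sd_x^2 + sd_y^2) / 2), with the
    across-subject SDs of each condition (not the SD of the differences).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.sqrt((x.std(ddof=1) ** 2 + y.std(ddof=1) ** 2) / 2.0)
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def paired_t_bonferroni(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    fwer: float = 0.05,
    value: str = "value",
) -> list[StatResult]:
    """Paired t per condition pair, Bonferroni-corrected over the family.

    Each p is multiplied by the number of pairs (capped at 1); the reported
    effect size is Cohen's d with the two conditions' pooled SD.
    """
    wide = _pivot(table, value)
    if wide.shape[0] < 2:
        raise ValidationError("need >= 2 subjects")
    m = len(pairs)
    out = []
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            raise ValidationError(f"conditions {a!r}/{b!r} not in the table")
        x, y = wide[a].to_numpy(), wide[b].to_numpy()
        if np.allclose(x, y):
            t, p = 0.0, 1.0  # zero difference everywhere: no effect
        else:
            t, p = stats.ttest_rel(x, y)
        out.append(
            StatResult(
                name="t", value=float(t), df=len(x) - 1,
                p=float(min(1.0, p * m)), effect_size=cohens_d(x, y),
                effect_size_name="d", correction=f"bonferroni(m={m}, fwer={fwer})",
                comparison=f"{a} vs {b}",
            )
        )
    return out


def summarize_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean RT by condition, excluding incorrect trials."""
    required = {"subject", "condition", "rt", "correct"}
    if not required <= set(trials.columns):
        raise ValidationError(f"trial table needs columns {sorted(required)}")
    ok = trials[trials["correct"].astype(bool)]
    out = ok.groupby(["subject", "condition"])["rt"].mean().reset_index()
    return out.rename(columns={"rt": "value"})


def read_source_workbook(
    path: str | Path,
    sheet: str,
    subject_column: str | None = None,
) -> pd.DataFrame:
    """Read one sheet of a source-data workbook into tidy long format.

    Expects one column per condition (plus an optional subject-id column);
    returns columns ``subject``, ``condition``, ``value``. A missing sheet
    raises an error listing the sheets available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"workbook not found: {path}")
    xls = pd.ExcelFile(path)
    if sheet not in xls.sheet_names:
        raise ValidationError(
            f"sheet {sheet!r} not in workbook; available: {xls.sheet_names}"
        )
    df = xls.parse(sheet)
    df = df.dropna(axis=1, how="all").dropna(axis=0, how="all")
    if subject_column and subject_column in df.columns:
        df = df.set_index(subject_column)
    else:
        lowered = [c for c in df.columns if str(c).strip().lower() in ("subject", "subj", "id")]
        if lowered:
            df = df.set_index(lowered[0])
    df.index = range(1, len(df) + 1)
    long = df.reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="value"
    )
    long = long.dropna(subset=["value"])
    long["value"] = long["value"].astype(float)
    return long
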