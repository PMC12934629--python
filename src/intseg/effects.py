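"""Paired effect sizes, two-sided t-tests, and Benjamini-Hochberg FDR control.

Every altered-state recording is compared with the same subject's baseline.
Effect size is Cohen's d for paired samples in the d_z convention:
d = mean(diff) / sd(diff) with the n-1 sample standard deviation; the paired
t statistic is then t = d * sqrt(n), and the large-sample standard error of d
is se_d = sqrt(1/n + d^2 / (2 n)).  p-values come from the t distribution with
n - 1 degrees of freedom, two-sided.  FDR adjustment is applied within each
metric x level family by default (one family per results panel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: FDR family choices: one family per metric x level panel, per metric, or all rows
FDR_FAMILIES = ("metric_level", "metric", "all")


@dataclass(frozen=True)
class PairedEffect:
    d: float
    se_d: float
    t: float
    p: float
    n: int

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.d)


def paired_effect(baseline: np.ndarray, altered: np.ndarray) -> PairedEffect:
    """Paired Cohen's d (d_z), its SE, and the two-sided paired t-test.

    Zero-variance differences make the effect undefined (all-NaN result with
    n preserved), mirroring the degenerate altered == baseline case.
    """
    baseline = np.asarray(baseline, dtype=float)
    altered = np.asarray(altered, dtype=float)
    if baseline.shape != altered.shape or baseline.ndim != 1:
        raise ValueError("baseline and altered must be aligned 1-D arrays")
    n = baseline.size
    if n < 3:
        raise ValueError("paired effect needs n >= 3 subjects")
    diff = altered - baseline
    sd = diff.std(ddof=1)
    if sd == 0:
        return PairedEffect(float("nan"), float("nan"), float("nan"), float("nan"), n)
    d = float(diff.mean() / sd)
    t = d * np.sqrt(n)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    se_d = float(np.sqrt(1.0 / n + d**2 / (2.0 * n)))
    return PairedEffect(d, se_d, float(t), p, n)


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs pass through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if valid.any():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def build_effect_table(
    results: pd.DataFrame, fdr_family: str = "metric_level"
) -> pd.DataFrame:
    """One paired effect per state x metric x level x contrast.

    ``results`` is the long-format per-recording table with columns
    subject, state, class, metric, level, contrast, value; baseline recordings
    carry state == "baseline".  Each altered value is paired with the same
    subject's baseline value for the identical metric/level/contrast.
    """
    if fdr_family not in FDR_FAMILIES:
        raise ValueError(f"fdr_family must be one of {FDR_FAMILIES}")
    required = {"subject", "state", "class", "metric", "level", "contrast", "value"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table is missing columns: {sorted(missing)}")

    base = results[results["state"] == "baseline"]
    alt = results[results["state"] != "baseline"]
    base_lookup = base.set_index(["subject", "metric", "level", "contrast"])["value"]
    if base_lookup.index.has_duplicates:
        dupes = base_lookup.index[base_lookup.index.duplicated()][:3].tolist()
        raise ValueError(f"duplicate baseline rows, e.g. {dupes}")

    rows = []
    group_cols = ["state", "class", "metric", "level", "contrast"]
    for (state, cls, metric, level, contrast), grp in alt.groupby(
        group_cols, sort=False
    ):
        keys = [(s, metric, level, contrast) for s in grp["subject"]]
        try:
            baseline_vals = base_lookup.loc[keys].to_numpy()
        except KeyError:
            have = {k[0] for k in keys if k in base_lookup.index}
            lost = sorted(set(grp["subject"]) - have)
            raise ValueError(
                f"missing baseline partner for subject(s) {lost[:5]} "
                f"in {metric}/{level}/{contrast}"
            ) from None
        eff = paired_effect(baseline_vals, grp["value"].to_numpy())
        rows.append(
            {
                "state": state,
                "class": cls,
                "metric": metric,
                "level": level,
                "contrast": contrast,
                "n": eff.n,
                "d": eff.d,
                "se_d": eff.se_d,
                "t": eff.t,
                "p": eff.p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no altered-state rows in results table")

    if fdr_family == "all":
        table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
    else:
        fam_cols = ["metric"] if fdr_family == "metric" else ["metric", "level"]
        table["p_fdr"] = (
            table.groupby(fam_cols, sort=False)["p"]
            .transform(lambda s: fdr_adjust(s.to_numpy()))
        )
    table["sig_fdr"] = table["p_fdr"] < 0.05
    table["sig_raw"] = table["p"] < 0.05
    return table
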