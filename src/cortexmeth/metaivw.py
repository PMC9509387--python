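"""Fixed-effects inverse-variance-weighted meta-analysis of EWAS summaries.

Each cohort contributes a per-probe table of (effect, se, n); probes kept
are those with usable statistics in at least ``min_cohorts`` cohorts.  The
pooled estimate is the inverse-variance weighted mean with
SE = (sum of weights)^(-1/2); heterogeneity (Cochran's Q, I^2) is reported
but plays no role in inference.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm


class BonferroniThreshold(NamedTuple):
    threshold: float  # full-precision alpha / n_tests
    display: float    # rounded to the requested significant digits


def _as_cohort_frame(df):
    need = {"effect", "se"}
    if not need <= set(df.columns):
        raise ValueError("cohort table needs 'effect' and 'se' columns")
    if df.index.duplicated().any():
        raise ValueError("duplicate probe IDs within a cohort")
    return df


def harmonize_probes(cohorts: dict, min_cohorts=2) -> pd.Index:
    """Probes with non-missing effect and positive SE in >= min_cohorts."""
    if len(cohorts) == 0:
        raise ValueError("need at least one cohort")
    if min_cohorts > len(cohorts):
        raise ValueError("min_cohorts exceeds the number of cohorts")
    counts = {}
    for df in cohorts.values():
        df = _as_cohort_frame(df)
        usable = df.index[df["effect"].notna() & (df["se"] > 0)]
        for probe in usable:
            counts[probe] = counts.get(probe, 0) + 1
    universe = pd.Index(sorted(p for p, c in counts.items() if c >= min_cohorts))
    if len(universe) == 0:
        raise ValueError("no probes present in enough cohorts")
    return universe


def ivw_meta(cohorts: dict, min_cohorts=2) -> pd.DataFrame:
    """Per-probe fixed-effects IVW pooling across cohorts.

    pooled effect = sum(w_i e_i) / sum(w_i), w_i = 1/se_i^2;
    pooled SE = (sum w_i)^(-1/2); z and two-sided normal p follow.
    """
    universe = harmonize_probes(cohorts, min_cohorts=min_cohorts)
    names = list(cohorts)
    eff = pd.DataFrame(index=universe, columns=names, dtype=float)
    se = pd.DataFrame(index=universe, columns=names, dtype=float)
    for name, df in cohorts.items():
        df = _as_cohort_frame(df)
        shared = df.index.intersection(universe)
        eff.loc[shared, name] = df.loc[shared, "effect"]
        se.loc[shared, name] = df.loc[shared, "se"]
    se = se.where(se > 0)  # non-positive SEs contribute nothing
    eff = eff.where(se.notna())

    w = 1.0 / se ** 2
    wsum = w.sum(axis=1)
    pooled = (w * eff).sum(axis=1) / wsum
    pooled_se = 1.0 / np.sqrt(wsum)
    z = pooled / pooled_se
    n_cohorts = w.notna().sum(axis=1)

    q = (w * (eff.sub(pooled, axis=0)) ** 2).sum(axis=1)
    dfree = (n_cohorts - 1).clip(lower=0)
    q_p = chi2.sf(q, dfree.where(dfree > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.maximum((q - dfree) / q, 0.0)
    i2 = np.where(dfree > 0, i2, np.nan)

    contributing = se.notna().apply(
        lambda row: ",".join(n for n in names if row[n]), axis=1)
    out = pd.DataFrame({
        "pooled_effect": pooled, "pooled_se": pooled_se, "z": z,
        "p_value": 2 * norm.sf(np.abs(z)), "n_cohorts": n_cohorts,
        "cohort_ids": contributing, "q": q, "q_p": q_p, "i2": i2,
    })
    out.index.name = "probe_id"
    return out


def bonferroni_threshold(alpha, n_tests, sig_digits=3) -> BonferroniThreshold:
    """alpha / n_tests, with a display value at ``sig_digits`` significant
    digits (the full-precision value is what thresholding should use)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n_tests
    exponent = np.floor(np.log10(abs(threshold)))
    factor = 10.0 ** (sig_digits - 1 - exponent)
    # round half up, matching how thresholds are conventionally printed
    display = np.floor(threshold * factor + 0.5) / factor
    return BonferroniThreshold(threshold, float(display))
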