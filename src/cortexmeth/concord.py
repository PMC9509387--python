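"""Direction concordance between result sets and sorted-fraction contrasts.

Covers the replication-style checks used when comparing EWAS outputs:
exact one-sided binomial sign tests of effect-direction agreement,
hyper/hypomethylation enrichment, high-vs-low pathology group EWAS in
purified nuclei fractions, and effect-size fold-change between a bulk
reference and a purified fraction (the amplification expected when a
bulk signal is confined to a minority cell type).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .ewas import vectorized_ols


def sign_test(k_concordant, n) -> float:
    """One-sided exact binomial upper tail P(X >= k), X ~ Bin(n, 1/2).

    Computed in exact integer arithmetic, so full concordance reduces to
    0.5**n without underflow for any practical n.
    """
    k, n = int(k_concordant), int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    total = sum(comb(n, i) for i in range(k, n + 1))
    return float(Fraction(total, 2 ** n))


def direction_enrichment(k_positive, n) -> float:
    """One-sided enrichment of one effect direction (e.g. hypermethylated
    with pathology) among n sites; same computation as the sign test,
    exposed separately for report labeling."""
    return sign_test(k_positive, n)


@dataclass
class ConcordanceReport:
    n_sites: int
    n_concordant: int
    fraction_concordant: float
    sign_p: float
    mean_fold_change: float
    n_zero_reference: int      # sites excluded from fold-change (ref effect 0)
    per_site: pd.DataFrame

    def summary(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_concordant": self.n_concordant,
            "fraction_concordant": self.fraction_concordant,
            "sign_p": self.sign_p,
            "mean_fold_change": self.mean_fold_change,
            "n_zero_reference": self.n_zero_reference,
        }


def high_low_group_ewas(beta_fraction: pd.DataFrame, labels: pd.DataFrame,
                        covariates=("age", "sex", "batch")) -> pd.DataFrame:
    """Per-site OLS of methylation on high/low pathology group.

    ``labels`` indexes the samples of ``beta_fraction`` (columns) or their
    donors; must contain ``group`` in {low, high} plus the covariates.
    Effect is the high-minus-low difference in percentage points.
    """
    lab = labels.copy()
    if not lab.index.isin(beta_fraction.columns).all():
        # allow donor-indexed labels against donor-prefixed sample columns
        mapping = {}
        for col in beta_fraction.columns:
            hits = [d for d in lab.index if str(col).startswith(str(d))]
            if len(hits) == 1:
                mapping[col] = hits[0]
        if len(mapping) != beta_fraction.shape[1]:
            raise ValueError("labels do not match beta_fraction samples")
        lab = lab.loc[[mapping[c] for c in beta_fraction.columns]]
        lab.index = beta_fraction.columns
    else:
        lab = lab.loc[beta_fraction.columns]
    groups = set(lab["group"])
    if groups != {"low", "high"}:
        raise ValueError("group must take values 'low' and 'high'")
    if (lab["group"].value_counts() < 3).any():
        raise ValueError("need at least 3 samples per group")

    cols = [np.ones(len(lab)), (lab["group"] == "high").astype(float).to_numpy()]
    names = ["Intercept", "group_high"]
    for c in covariates:
        if c == "sex":
            cols.append((lab["sex"].astype(str) == "M").astype(float).to_numpy())
            names.append("sex_M")
        elif c == "batch":
            d = pd.get_dummies(lab["batch"].astype("category"),
                               prefix="batch", drop_first=True, dtype=float)
            for name in d.columns:
                cols.append(d[name].to_numpy())
                names.append(name)
        else:
            cols.append(lab[c].astype(float).to_numpy())
            names.append(c)
    X = np.column_stack(cols)
    j = names.index("group_high")

    Y = beta_fraction.to_numpy(dtype=float)
    ok = np.nanstd(Y, axis=1) > 0
    rows = []
    if ok.any():
        B, se, tstat, pvals = vectorized_ols(Y[ok], X)
        for i, site in enumerate(beta_fraction.index[ok]):
            rows.append((site, B[i, j] * 100, se[i, j] * 100, tstat[i, j],
                         pvals[i, j], len(lab), ""))
    for site in beta_fraction.index[~ok]:
        rows.append((site, np.nan, np.nan, np.nan, np.nan, len(lab),
                     "skipped: zero variance"))
    out = pd.DataFrame(rows, columns=["probe_id", "effect", "se", "statistic",
                                      "p_value", "n_samples", "flag"]
                       ).set_index("probe_id")
    out["model_label"] = "high_vs_low"
    return out.loc[beta_fraction.index]


def concordance_report(reference_results: pd.DataFrame,
                       fraction_results: pd.DataFrame,
                       site_set=None, ratio_of_means=False) -> ConcordanceReport:
    """Direction concordance and effect amplification between result sets.

    Concordance is agreement in effect sign at each shared site; its
    one-sided sign-test p treats agreement as the success direction.
    Fold-change is the mean over sites of |effect_fraction|/|effect_ref|
    (sites with a reference effect of exactly 0 are excluded and
    counted); ``ratio_of_means=True`` instead uses
    mean|effect_fraction| / mean|effect_ref|.
    """
    shared = reference_results.index.intersection(fraction_results.index)
    if site_set is not None:
        shared = shared.intersection(pd.Index(site_set))
    if len(shared) == 0:
        raise ValueError("no shared sites between the result sets")
    a = reference_results.loc[shared, "effect"].to_numpy(dtype=float)
    b = fraction_results.loc[shared, "effect"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b, shared = a[ok], b[ok], shared[ok]

    concordant = np.sign(a) == np.sign(b)
    n = len(shared)
    k = int(concordant.sum())
    nonzero = a != 0
    ratios = np.abs(b[nonzero]) / np.abs(a[nonzero])
    if ratio_of_means:
        fold = float(np.abs(b[nonzero]).mean() / np.abs(a[nonzero]).mean())
    else:
        fold = float(ratios.mean()) if nonzero.any() else np.nan
    per_site = pd.DataFrame({
        "effect_reference": a, "effect_fraction": b,
        "concordant": concordant,
        "fold_change": np.where(a != 0, np.abs(b) / np.where(a == 0, np.nan, np.abs(a)), np.nan),
    }, index=shared)
    return ConcordanceReport(
        n_sites=n, n_concordant=k, fraction_concordant=k / n,
        sign_p=sign_test(k, n), mean_fold_change=fold,
        n_zero_reference=int((~nonzero).sum()), per_site=per_site)
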