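"""Reference-based cell-type deconvolution of bulk cortex methylation.

Builds a panel of discriminating CpGs from labeled nuclei-population
reference samples (one-way ANOVA selection, equal numbers of hyper- and
hypomethylated sites per cell type) and estimates per-sample cell
proportions by constrained least squares: pi >= 0, sum(pi) <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .qcnorm import quantile_normalize

#: weight of the penalty row enforcing sum(pi) = 1 when that constraint
#: is active; violation scales as 1/weight^2, far below the 1e-9 tolerance
_PENALTY = 1e6
_SUM_TOL = 1e-9


@dataclass
class ReferencePanel:
    """Discriminating-site panel: mean reference beta per cell type plus
    the defining cell type, direction, and ANOVA statistics per site."""
    sites: pd.DataFrame      # index site_id; columns celltype, direction, f_stat, p_value
    mean_beta: pd.DataFrame  # index site_id; one column per cell type

    @property
    def site_ids(self):
        return list(self.sites.index)

    @property
    def celltype_names(self):
        return list(self.mean_beta.columns)

    def to_frame(self) -> pd.DataFrame:
        return self.sites.join(self.mean_beta)


@dataclass
class CellProportions:
    proportions: pd.DataFrame  # index sample_id; one column per cell type
    residual_norm: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.proportions.copy()
        out["residual_norm"] = self.residual_norm
        return out


def anova_f(values_by_group):
    """One-way ANOVA F statistic and upper-tail p across >=2 groups."""
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    n = sum(len(g) for g in groups)
    if n - len(groups) <= 0:
        raise ValueError("zero within-group degrees of freedom")
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def _anova_all_probes(values, label_codes, n_groups):
    """Vectorized one-way ANOVA across all probes (rows of ``values``)."""
    n = values.shape[1]
    grand = values.mean(axis=1)
    ss_between = np.zeros(len(values))
    ss_within = np.zeros(len(values))
    for g in range(n_groups):
        cols = label_codes == g
        ng = cols.sum()
        mg = values[:, cols].mean(axis=1)
        ss_between += ng * (mg - grand) ** 2
        ss_within += ((values[:, cols] - mg[:, None]) ** 2).sum(axis=1)
    df_b, df_w = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    F = np.where(ss_within == 0, np.inf, F)
    p = stats.f.sf(F, df_b, df_w)
    return F, p


def select_discriminating_sites(ref_beta: pd.DataFrame, celltype_labels,
                                p_cut=1e-8, per_type=100) -> ReferencePanel:
    """Select ``per_type`` discriminating sites per cell type.

    Among probes with ANOVA p below ``p_cut``, each probe is assigned to
    the cell type where its contrast (mean in that type minus mean of the
    others) is largest in magnitude; per cell type the ``per_type/2``
    largest positive contrasts become "hyper" sites and the ``per_type/2``
    most negative become "hypo" sites, with ties broken by F statistic and
    then probe ID so the panel is fully deterministic.
    """
    labels = pd.Series(celltype_labels, index=ref_beta.columns)
    celltypes = list(pd.unique(labels))
    if len(celltypes) < 2:
        raise ValueError("need at least 2 cell types")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 reference samples per cell type")
    if per_type % 2:
        raise ValueError("per_type must be even")

    V = ref_beta.to_numpy(dtype=float)
    codes = labels.map({c: i for i, c in enumerate(celltypes)}).to_numpy()
    F, p = _anova_all_probes(V, codes, len(celltypes))

    means = np.column_stack([V[:, codes == g].mean(axis=1)
                             for g in range(len(celltypes))])
    contrasts = np.column_stack([
        means[:, g] - np.delete(means, g, axis=1).mean(axis=1)
        for g in range(len(celltypes))])

    eligible = p < p_cut
    assigned = np.abs(contrasts).argmax(axis=1)

    half = per_type // 2
    rows = []
    for g, ct in enumerate(celltypes):
        pool = np.nonzero(eligible & (assigned == g))[0]
        sub = pd.DataFrame({
            "probe": ref_beta.index[pool],
            "contrast": contrasts[pool, g],
            "f_stat": F[pool],
            "p_value": p[pool],
        })
        hyper = sub[sub["contrast"] > 0].sort_values(
            ["contrast", "f_stat", "probe"], ascending=[False, False, True])
        hypo = sub[sub["contrast"] < 0].sort_values(
            ["contrast", "f_stat", "probe"], ascending=[True, False, True])
        if len(hyper) < half or len(hypo) < half:
            raise ValueError(
                f"insufficient discriminating sites for {ct}: "
                f"{len(hyper)} hyper / {len(hypo)} hypo available, "
                f"{half} of each required")
        for direction, block in (("hyper", hyper.head(half)),
                                 ("hypo", hypo.head(half))):
            for _, r in block.iterrows():
                rows.append((r["probe"], ct, direction, r["f_stat"], r["p_value"]))

    sites = pd.DataFrame(rows, columns=["site_id", "celltype", "direction",
                                        "f_stat", "p_value"]).set_index("site_id")
    mean_beta = pd.DataFrame(means, index=ref_beta.index,
                             columns=celltypes).loc[sites.index]
    return ReferencePanel(sites, mean_beta)


def _solve_constrained(R, m):
    """min ||m - R pi|| s.t. pi >= 0, sum(pi) <= 1.

    An unconstrained NNLS solution satisfying the sum constraint is the
    optimum (the constraint is inactive); otherwise the constraint binds
    and the problem is re-solved with a heavily weighted penalty row
    enforcing sum(pi) = 1.
    """
    pi, _ = nnls(R, m)
    if pi.sum() > 1 + _SUM_TOL:
        A = np.vstack([R, _PENALTY * np.ones(R.shape[1])])
        b = np.append(m, _PENALTY)
        pi, _ = nnls(A, b)
        if pi.sum() > 1:
            pi = pi / pi.sum()
    resid = float(np.linalg.norm(m - R @ pi))
    return pi, resid


def estimate_proportions(bulk_beta: pd.DataFrame, panel: ReferencePanel,
                         min_coverage=0.9) -> CellProportions:
    """Estimate per-sample cell proportions over the panel sites."""
    present = panel.mean_beta.index.intersection(bulk_beta.index)
    coverage = len(present) / len(panel.mean_beta)
    if coverage < min_coverage:
        raise ValueError(
            f"only {coverage:.0%} of panel sites present in bulk matrix "
            f"(need >= {min_coverage:.0%})")
    if coverage < 1:
        warnings.warn(f"{len(panel.mean_beta) - len(present)} panel sites "
                      "missing from bulk matrix; proceeding on the rest")
    R = panel.mean_beta.loc[present].to_numpy(dtype=float)
    M = bulk_beta.loc[present].to_numpy(dtype=float)

    out = np.zeros((bulk_beta.shape[1], R.shape[1]))
    resid = np.zeros(bulk_beta.shape[1])
    for j in range(bulk_beta.shape[1]):
        m = M[:, j]
        ok = ~np.isnan(m)
        out[j], resid[j] = _solve_constrained(R[ok], m[ok])
    props = pd.DataFrame(out, index=bulk_beta.columns,
                         columns=panel.celltype_names)
    return CellProportions(props, pd.Series(resid, index=bulk_beta.columns,
                                            name="residual_norm"))


def joint_normalize_and_estimate(bulk_beta: pd.DataFrame,
                                 ref_beta: pd.DataFrame, celltype_labels,
                                 p_cut=1e-8, per_type=100,
                                 min_coverage=0.9) -> CellProportions:
    """Quantile-normalize reference and bulk together, rebuild the panel
    on the normalized reference, then estimate proportions on the
    normalized bulk.  Brings bulk data onto the reference scale before
    deconvolution, mirroring reference-based estimation pipelines."""
    shared = ref_beta.index.intersection(bulk_beta.index)
    if len(shared) == 0:
        raise ValueError("reference and bulk share no probes")
    combined = pd.concat([ref_beta.loc[shared], bulk_beta.loc[shared]], axis=1)
    normed = quantile_normalize(combined)
    ref_n = normed.iloc[:, :ref_beta.shape[1]]
    bulk_n = normed.iloc[:, ref_beta.shape[1]:]
    panel = select_discriminating_sites(ref_n, celltype_labels,
                                        p_cut=p_cut, per_type=per_type)
    return estimate_proportions(bulk_n, panel, min_coverage=min_coverage)
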