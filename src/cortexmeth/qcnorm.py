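"""Matrix-level QC and between-sample quantile normalization.

Operates on beta matrices laid out probes x samples (pandas DataFrames,
probe IDs as index, sample IDs as columns), mirroring the layout of
methylation-array processing pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation, rankdata


@dataclass
class QCReport:
    """Record of what a QC step removed and why."""
    samples_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"]))
    probes_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["probe_id", "reason"]))
    outlier_scores: pd.DataFrame | None = None

    @property
    def n_samples_removed(self):
        return len(self.samples_removed)

    @property
    def n_probes_removed(self):
        return len(self.probes_removed)

    def summary(self) -> dict:
        return {
            "samples_removed": list(self.samples_removed["sample_id"]),
            "probes_removed": list(self.probes_removed["probe_id"]),
        }


def _check_aligned(beta, detp):
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        raise ValueError("beta and detection-p matrices must share axes")


def pfilter(beta: pd.DataFrame, detp: pd.DataFrame, detp_cut=0.05,
            sample_frac=0.01, probe_frac=0.01):
    """Detection-p filtering of samples then probes.

    A sample is excluded when strictly more than ``sample_frac`` of its
    probes have detection p above ``detp_cut``; probe failure fractions
    are then recomputed on the retained samples and probes failing in
    strictly more than ``probe_frac`` of them are excluded.
    """
    _check_aligned(beta, detp)
    fail = detp.to_numpy() > detp_cut
    sample_fail_frac = fail.mean(axis=0)
    bad_samples = beta.columns[sample_fail_frac > sample_frac]
    keep_cols = beta.columns.difference(bad_samples, sort=False)

    fail_kept = fail[:, beta.columns.get_indexer(keep_cols)]
    probe_fail_frac = fail_kept.mean(axis=1) if len(keep_cols) else np.zeros(len(beta))
    bad_probes = beta.index[probe_fail_frac > probe_frac]
    keep_rows = beta.index.difference(bad_probes, sort=False)

    report = QCReport(
        samples_removed=pd.DataFrame({
            "sample_id": bad_samples,
            "reason": [f">{sample_frac:.0%} probes with detection p>{detp_cut}"] * len(bad_samples)}),
        probes_removed=pd.DataFrame({
            "probe_id": bad_probes,
            "reason": [f">{probe_frac:.0%} retained samples with detection p>{detp_cut}"] * len(bad_probes)}),
    )
    return beta.loc[keep_rows, keep_cols], report


def _robust_z(x):
    med = np.median(x)
    mad = median_abs_deviation(x, scale="normal")
    if mad == 0:
        sd = x.std(ddof=1)
        if sd == 0:
            return np.zeros_like(x)
        return (x - med) / sd
    return (x - med) / mad


def _pc_scores(values, n_pcs):
    # samples x probes; mean-impute missing per probe for the decomposition
    X = values.T.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, len(s))
    return u[:, :k] * s[:k]


def pc_outlier_removal(beta: pd.DataFrame, n_pcs=3, z_cut=3.0):
    """Remove samples that are outliers on any of the first ``n_pcs``
    principal components (robust z via median/MAD), with a single repeat
    pass on the retained samples.  Never removes more than half the
    samples; raises if every sample would be removed."""
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if beta.shape[1] < 4:
        raise ValueError("need at least 4 samples for PC outlier removal")
    max_removed = beta.shape[1] // 2
    removed, score_frames = [], []
    current = beta
    for _ in range(2):  # initial pass + one iteration
        scores = _pc_scores(current.to_numpy(dtype=float), n_pcs)
        z = np.column_stack([_robust_z(scores[:, j]) for j in range(scores.shape[1])])
        score_frames.append(pd.DataFrame(
            z, index=current.columns,
            columns=[f"PC{j+1}_z" for j in range(z.shape[1])]))
        is_out = (np.abs(z) > z_cut).any(axis=1)
        if not is_out.any():
            break
        out_ids = list(current.columns[is_out])
        if len(removed) + len(out_ids) > max_removed:
            out_ids = out_ids[:max_removed - len(removed)]
        removed.extend(out_ids)
        current = current.drop(columns=out_ids)
        if current.shape[1] == 0:
            raise ValueError("PC outlier removal would remove all samples")
        if len(removed) >= max_removed:
            break
    report = QCReport(
        samples_removed=pd.DataFrame({
            "sample_id": removed,
            "reason": [f"|robust z|>{z_cut} on a top-{n_pcs} PC"] * len(removed)}),
        outlier_scores=score_frames[0],
    )
    return current, report


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the mean-of-sorted-samples distribution.

    Ties receive the mean of the values they would have received; missing
    values stay missing and are excluded from rank computation (columns
    with fewer observed values are mapped through interpolated quantiles
    of the reference distribution).
    """
    if beta.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    V = beta.to_numpy(dtype=float)
    n_probes, n_samples = V.shape
    obs_counts = (~np.isnan(V)).sum(axis=0)
    if (obs_counts < 1).any():
        raise ValueError("a sample has no observed values")

    # reference distribution on a common grid of plotting positions
    grid = (np.arange(n_probes) + 0.5) / n_probes
    ref = np.zeros(n_probes)
    for j in range(n_samples):
        col = np.sort(V[~np.isnan(V[:, j]), j])
        nj = len(col)
        if nj == n_probes:
            ref += col
        else:
            pos = (np.arange(nj) + 0.5) / nj
            ref += np.interp(grid, pos, col)
    ref /= n_samples

    out = np.full_like(V, np.nan)
    for j in range(n_samples):
        mask = ~np.isnan(V[:, j])
        nj = mask.sum()
        ranks = rankdata(V[mask, j], method="average")
        out[mask, j] = np.interp((ranks - 0.5) / nj, grid, ref)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def compute_pc1(beta: pd.DataFrame, n_top_variable=10000) -> pd.Series:
    """First principal-component score per sample, computed on the most
    variable probes; the loading sign is fixed so the loadings sum to a
    non-negative value (invariant to the SVD's arbitrary sign)."""
    if beta.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    V = beta.to_numpy(dtype=float)
    variances = np.nanvar(V, axis=1)
    if len(beta) > n_top_variable:
        top = np.argsort(variances)[::-1][:n_top_variable]
        V = V[np.sort(top), :]
    X = V.T.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, 0] * s[0]
    if vt[0].sum() < 0:
        scores = -scores
    return pd.Series(scores, index=beta.columns, name="pc1")
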