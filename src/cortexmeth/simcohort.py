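"""Synthetic cortical methylation cohorts with known ground truth.

This module generates every input the rest of the pipeline consumes:

* cell-type reference profiles with planted discriminating CpGs,
* correlated ordinal neuropathology measures (latent-Gaussian copula),
* bulk two-region cohorts where cell proportions drift with tau pathology
  in the prefrontal cortex only and differential methylation is confined
  to chosen cell types,
* sorted-nuclei fraction studies contrasting low- and high-pathology donors.

The central mechanism being emulated is signal attenuation by cell-type
mixing: an effect of size ``d`` confined to a cell type present at mean
proportion ``pi`` appears in bulk tissue at size ``pi * d``.  All
generators are pure functions of their arguments and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

CELLTYPES = ("NeuN+", "SOX10+", "DN")
REGIONS = ("DLPFC", "OCC")
PATHOLOGY_MEASURES = ("braak_nft", "cerad", "thal", "braak_lb", "tdp43")

#: ordinal range (max value) of each measure; tdp43 is binary
MEASURE_MAX = {"braak_nft": 6, "cerad": 3, "thal": 5, "braak_lb": 6, "tdp43": 1}

#: cohort-level marginal means of the five measures (defaults emulate an
#: aged brain-bank population with substantial AD pathology)
DEFAULT_MEASURE_MEANS = {
    "braak_nft": 3.72,
    "cerad": 1.69,
    "thal": 3.09,
    "braak_lb": 1.34,
    "tdp43": 0.22,
}

#: per-Braak-stage drift of cell proportions (percentage points per stage)
#: applied in DLPFC only: neuronal loss, relative oligodendrocyte gain,
#: microglia/astrocyte (double-negative, "DN") loss
DEFAULT_PROPORTION_COUPLING = {"NeuN+": -2.74, "SOX10+": 1.60, "DN": -2.00}

#: mean cell-type composition of bulk cortex used by the generators; the
#: residual mass (here 0.14) is unlabeled debris carrying the background
#: methylation profile, giving the pathology-coupled shifts (which do not
#: sum to zero) somewhere to go without changing total DNA mass
DEFAULT_BASE_PROPORTIONS = {"NeuN+": 0.40, "SOX10+": 0.35, "DN": 0.11}

_EPS = 1e-12


def _rng(seed):
    return np.random.default_rng(seed)


def _logit_normal_noise(beta, sd, rng):
    """Add Gaussian noise on the logit scale; keeps values inside (0, 1)."""
    if np.isscalar(sd) and sd == 0:
        return np.asarray(beta, dtype=float).copy()
    z = logit(np.clip(beta, _EPS, 1 - _EPS))
    return expit(z + rng.normal(0.0, sd, size=np.shape(beta)))


# ---------------------------------------------------------------------------
# reference profiles
# ---------------------------------------------------------------------------

@dataclass
class CellTypeProfiles:
    """Per-cell-type mean methylation with planted discriminating sites.

    ``mean_beta`` is probes x cell types; ``discriminating_mask`` flags, for
    each probe, the cell type (if any) in which it was planted to differ
    from the others by at least ``separation``.
    """

    probe_ids: list
    celltype_names: list
    mean_beta: np.ndarray
    within_type_sd: np.ndarray
    discriminating_mask: np.ndarray
    separation: float

    def __post_init__(self):
        self.mean_beta = np.asarray(self.mean_beta, dtype=float)
        if self.mean_beta.min() < 0 or self.mean_beta.max() > 1:
            raise ValueError("mean_beta must lie in [0, 1]")
        if np.any(np.asarray(self.within_type_sd) <= 0):
            raise ValueError("within_type_sd must be positive")

    @property
    def n_probes(self):
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_beta, index=self.probe_ids,
                            columns=self.celltype_names)


def make_reference_profiles(n_probes, n_celltypes=3, n_discriminating_per_type=100,
                            separation=0.5, seed=None, celltype_names=None):
    """Construct cell-type mean-methylation profiles.

    Exactly ``n_discriminating_per_type`` probes per cell type are planted:
    half shifted up ("hyper") and half down ("hypo") by ``separation`` in
    that cell type relative to the common background mean shared by the
    remaining cell types.  All other probes are identical across types.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    margin = 0.02
    if separation >= 1 - 2 * margin:
        raise ValueError(
            f"separation={separation} cannot keep shifted means inside [0, 1]")
    if celltype_names is None:
        celltype_names = list(CELLTYPES[:n_celltypes]) if n_celltypes <= 3 else [
            f"CT{i+1}" for i in range(n_celltypes)]
    if len(celltype_names) != n_celltypes:
        raise ValueError("celltype_names length must equal n_celltypes")
    n_disc_total = n_discriminating_per_type * n_celltypes
    if n_disc_total > n_probes:
        raise ValueError("more discriminating sites requested than probes")
    if n_discriminating_per_type % 2:
        raise ValueError("n_discriminating_per_type must be even (half hyper, half hypo)")

    rng = _rng(seed)
    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    base = rng.uniform(margin, 1 - margin, size=n_probes)
    mean_beta = np.tile(base[:, None], (1, n_celltypes))
    mask = np.zeros((n_probes, n_celltypes), dtype=bool)

    order = rng.permutation(n_probes)
    half = n_discriminating_per_type // 2
    pos = 0
    for c in range(n_celltypes):
        hyper = order[pos:pos + half]
        hypo = order[pos + half:pos + n_discriminating_per_type]
        pos += n_discriminating_per_type
        # hyper: background low enough that background + separation <= 1
        bg_hyper = rng.uniform(margin, 1 - separation - margin, size=half)
        mean_beta[hyper, :] = bg_hyper[:, None]
        mean_beta[hyper, c] = bg_hyper + separation
        # hypo: background high enough that background - separation >= 0
        bg_hypo = rng.uniform(separation + margin, 1 - margin, size=half)
        mean_beta[hypo, :] = bg_hypo[:, None]
        mean_beta[hypo, c] = bg_hypo - separation
        mask[hyper, c] = True
        mask[hypo, c] = True

    within_sd = rng.uniform(0.1, 0.4, size=n_probes)
    return CellTypeProfiles(probe_ids, list(celltype_names), mean_beta,
                            within_sd, mask, separation)


def make_reference_samples(profiles, n_per_type=12, seed=None):
    """Draw labeled nuclei-population samples around the profile means.

    Emulates the purified-nuclei reference experiment: ``n_per_type``
    replicate samples per cell type with logit-normal within-type noise at
    each probe's ``within_type_sd``.  Returns ``(beta, labels)`` where
    ``beta`` is probes x samples and ``labels`` gives each sample's type.
    """
    rng = _rng(seed)
    cols, labels = [], []
    mats = []
    for c, name in enumerate(profiles.celltype_names):
        mu = profiles.mean_beta[:, c]
        for r in range(n_per_type):
            mats.append(_logit_normal_noise(mu, profiles.within_type_sd, rng))
            cols.append(f"ref_{name}_{r:02d}")
            labels.append(name)
    beta = pd.DataFrame(np.column_stack(mats), index=profiles.probe_ids,
                        columns=cols)
    return beta, pd.Series(labels, index=cols, name="celltype")


# ---------------------------------------------------------------------------
# pathology
# ---------------------------------------------------------------------------

def default_pathology_correlation():
    """Latent correlation among the five measures: the three AD measures
    (tau tangles, neuritic plaques, amyloid phase) are strongly mutually
    correlated; Lewy-body and TDP-43 co-pathology only weakly so."""
    names = PATHOLOGY_MEASURES
    R = np.full((5, 5), 0.2)
    for i in range(3):
        for j in range(3):
            R[i, j] = 0.7
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=names, columns=names)


def _marginal_pmf(measure, mean):
    """Binomial pmf on the measure's ordinal range with the requested mean."""
    k = MEASURE_MAX[measure]
    p = mean / k
    if not 0 <= p <= 1:
        raise ValueError(f"mean {mean} outside range of {measure}")
    j = np.arange(k + 1)
    from scipy.stats import binom
    return binom.pmf(j, k, p)


def make_pathology(n_donors, correlation=None, means=None, seed=None):
    """Sample correlated ordinal neuropathology measures for ``n_donors``.

    A latent multivariate-Gaussian copula is thresholded into each
    measure's ordinal range; marginals are binomial with configurable
    means so the ordinal shape is unimodal around the cohort mean.
    """
    if correlation is None:
        correlation = default_pathology_correlation()
    R = np.asarray(correlation, dtype=float)
    if R.shape != (5, 5) or not np.allclose(R, R.T):
        raise ValueError("correlation must be a symmetric 5x5 matrix")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("correlation diagonal must be 1")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    means = {**DEFAULT_MEASURE_MEANS, **(means or {})}

    rng = _rng(seed)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(5))
    z = rng.standard_normal((n_donors, 5)) @ L.T
    u = norm.cdf(z)
    out = {}
    for j, m in enumerate(PATHOLOGY_MEASURES):
        pmf = _marginal_pmf(m, means[m])
        cum = np.cumsum(pmf)
        cum[-1] = 1.0
        out[m] = np.searchsorted(cum, u[:, j], side="left").astype(int)
    donors = [f"D{i:04d}" for i in range(n_donors)]
    return pd.DataFrame(out, index=pd.Index(donors, name="donor_id"))


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Differential methylation planted in one cell type.

    ``effect_per_unit`` holds per-probe magnitudes in percentage points of
    methylation per unit of ``driving_measure``; ``sign`` is +1 (hyper with
    pathology) or -1 per probe.  The effect enters only the target cell
    type's component of the mixture.
    """

    target_probes: list
    target_celltype: str
    effect_per_unit: np.ndarray
    sign: np.ndarray
    driving_measure: str = "braak_nft"

    def __post_init__(self):
        self.effect_per_unit = np.broadcast_to(
            np.asarray(self.effect_per_unit, dtype=float),
            (len(self.target_probes),)).copy()
        self.sign = np.broadcast_to(
            np.asarray(self.sign, dtype=float), (len(self.target_probes),)).copy()
        if not np.all(np.isin(self.sign, (-1.0, 1.0))):
            raise ValueError("sign must be +/-1 per probe")
        if self.driving_measure not in PATHOLOGY_MEASURES:
            raise ValueError(f"unknown driving measure {self.driving_measure}")

    @property
    def signed_effect(self):
        return self.effect_per_unit * self.sign


def make_effect_spec(target_probes, target_celltype, mean_effect=0.44,
                     sd_effect=0.17, p_hyper=0.5, driving_measure="braak_nft",
                     seed=None):
    """Draw per-probe effect magnitudes around ``mean_effect`` (percentage
    points per unit of the driving measure; defaults emulate the average
    per-Braak-stage bulk effect size) with signs hyper with probability
    ``p_hyper``."""
    rng = _rng(seed)
    n = len(target_probes)
    mag = np.abs(rng.normal(mean_effect, sd_effect, size=n))
    mag = np.maximum(mag, 1e-3)
    sign = np.where(rng.uniform(size=n) < p_hyper, 1.0, -1.0)
    return EffectSpec(list(target_probes), target_celltype, mag, sign,
                      driving_measure)


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

@dataclass
class TrueProportions:
    """Ground-truth per-sample cell proportions (for recovery tests)."""
    sample_ids: list
    celltype_names: list
    proportions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.sample_ids,
                            columns=self.celltype_names)


@dataclass
class SyntheticCohort:
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    phenotypes: pd.DataFrame
    true_proportions: pd.DataFrame
    effect_spec: EffectSpec | None = None


def _draw_proportions(rng, n, base_proportions, concentration):
    """Dirichlet draw over the labeled cell types plus an implicit debris
    component holding the residual mass ``1 - sum(base_proportions)``.
    An infinite concentration gives every donor exactly the base
    composition (useful for exact-algebra checks)."""
    names = list(base_proportions)
    base = np.array([base_proportions[c] for c in names], dtype=float)
    debris = 1.0 - base.sum()
    if debris < -1e-9:
        raise ValueError("base proportions must sum to at most 1")
    if not np.isfinite(concentration):
        return names, np.tile(base, (n, 1))
    alpha = np.append(base, debris) if debris > 1e-9 else base
    pi = rng.dirichlet(alpha * concentration, size=n)
    return names, pi[:, :len(base)]


def _draw_coupled_proportions(rng, base, concentration, shifts):
    """Per-donor Dirichlet draw with donor-specific mean composition.

    ``base`` is the cell-type mean vector (sum < 1, debris implicit);
    ``shifts`` (donors x cell types) moves each donor's expected
    composition, with debris absorbing the imbalance so the mean stays on
    the simplex.  Raises if any expected component is driven to zero.
    """
    n = shifts.shape[0]
    mean = np.empty((n, len(base) + 1))
    mean[:, :-1] = base[None, :] + shifts
    mean[:, -1] = 1.0 - mean[:, :-1].sum(axis=1)
    if mean.min() <= 1e-6:
        raise ValueError(
            "proportion coupling drove a cell proportion negative; "
            "reduce the coupling or adjust the base proportions")
    if not np.isfinite(concentration):
        return mean[:, :-1]
    g = rng.standard_gamma(concentration * mean)
    pi = g / g.sum(axis=1, keepdims=True)
    return pi[:, :-1]


def _background_profile(profiles):
    """Per-probe baseline shared by the unflagged cell types (the median
    across cell types); used as the methylation profile of debris mass."""
    return np.median(profiles.mean_beta, axis=1)


def make_cohort(profiles, n_donors=300, regions=REGIONS, effect_spec=None,
                proportion_coupling=None, base_proportions=None,
                proportion_concentration=150.0,
                noise_sd=0.1, donor_sd=0.05, detp_fail_rate=0.001,
                pathology_means=None, pathology_correlation=None, seed=None):
    """Generate a bulk two-region methylation cohort.

    Per donor, cell proportions are drawn from a Dirichlet whose mean is
    the cortical base composition, shifted linearly with Braak NFT stage
    in DLPFC only (centered at the realized cohort mean so average
    composition is unchanged); the debris component absorbs the shift
    imbalance, so draws always live in the simplex.  Bulk beta is the
    proportion-weighted mixture of cell-type profiles, with the residual
    (debris) mass contributing the per-probe background profile so total
    DNA mass is always 1.  Any ``effect_spec`` shift is applied inside
    the target cell type only.  A donor-level random intercept and
    residual noise are added on the logit scale.  Detection p-values are
    uniform near 0 with a ``detp_fail_rate`` point mass near 1.

    Raises if the pathology-coupled shifts drive any expected proportion
    (cell type or debris) non-positive (truncation is never silent).
    """
    regions = tuple(regions)
    if not set(regions) <= set(REGIONS):
        raise ValueError(f"regions must be a subset of {REGIONS}")
    if noise_sd < 0 or donor_sd < 0:
        raise ValueError("noise parameters must be non-negative")
    if proportion_coupling is None:
        proportion_coupling = DEFAULT_PROPORTION_COUPLING
    if base_proportions is None:
        base_proportions = DEFAULT_BASE_PROPORTIONS

    rng = _rng(seed)
    patho = make_pathology(n_donors, correlation=pathology_correlation,
                           means=pathology_means,
                           seed=rng.integers(2 ** 31))
    donors = list(patho.index)
    ct_names = list(base_proportions)
    base_vec = np.array([base_proportions[c] for c in ct_names], dtype=float)
    if base_vec.sum() > 1 + 1e-9:
        raise ValueError("base proportions must sum to at most 1")
    background = _background_profile(profiles)
    if ct_names != list(profiles.celltype_names):
        raise ValueError("base_proportions cell types must match profiles")

    braak = patho["braak_nft"].to_numpy(dtype=float)
    braak_centered = braak - braak.mean()
    coupling = np.array([proportion_coupling.get(c, 0.0) for c in ct_names]) / 100.0

    n_probes = profiles.n_probes
    probe_index = {p: i for i, p in enumerate(profiles.probe_ids)}
    target_rows = np.array([], dtype=int)
    if effect_spec is not None:
        target_rows = np.array([probe_index[p] for p in effect_spec.target_probes])
        tc = profiles.celltype_names.index(effect_spec.target_celltype)
        measure = patho[effect_spec.driving_measure].to_numpy(dtype=float)
        # probes x donors shift inside the target cell type (beta units)
        delta_td = np.outer(effect_spec.signed_effect / 100.0, measure)

    donor_re = rng.normal(0.0, donor_sd, size=(n_probes, n_donors)) if donor_sd > 0 else None

    sample_ids, beta_cols, detp_cols, prop_rows, pheno_rows = [], [], [], [], []
    age = np.clip(rng.normal(84, 7, size=n_donors), 41, 104).round(1)
    sex = np.where(rng.uniform(size=n_donors) < 0.53, "M", "F")
    batch = rng.integers(1, 9, size=n_donors)

    for r in regions:
        if r == "DLPFC":
            shifts = braak_centered[:, None] * coupling[None, :]
        else:
            shifts = np.zeros((n_donors, len(ct_names)))
        pi = _draw_coupled_proportions(rng, base_vec,
                                       proportion_concentration, shifts)
        resid = 1.0 - pi.sum(axis=1)
        # probes x donors mixture; debris carries the background profile
        bulk = profiles.mean_beta @ pi.T + np.outer(background, resid)
        if effect_spec is not None:
            bulk[target_rows, :] += delta_td * pi[:, tc][None, :]
        noisy = bulk
        if donor_re is not None:
            noisy = _logit_noise_matrix(noisy, donor_re, rng, noise_sd)
        elif noise_sd > 0:
            noisy = _logit_noise_matrix(noisy, None, rng, noise_sd)
        ids = [f"{d}_{r}" for d in donors]
        sample_ids.extend(ids)
        beta_cols.append(noisy)
        detp = rng.uniform(0.0, 0.01, size=(n_probes, n_donors))
        if detp_fail_rate > 0:
            fail = rng.uniform(size=(n_probes, n_donors)) < detp_fail_rate
            detp[fail] = rng.uniform(0.95, 1.0, size=fail.sum())
        detp_cols.append(detp)
        prop_rows.append(pi)
        pheno_rows.append(pd.DataFrame({
            "donor_id": donors, "region": r, "age": age, "sex": sex,
            "batch": batch,
            **{m: patho[m].to_numpy() for m in PATHOLOGY_MEASURES},
        }, index=ids))

    beta = pd.DataFrame(np.hstack(beta_cols), index=profiles.probe_ids,
                        columns=sample_ids)
    detp = pd.DataFrame(np.hstack(detp_cols), index=profiles.probe_ids,
                        columns=sample_ids)
    pheno = pd.concat(pheno_rows)
    pheno.index.name = "sample_id"
    props = pd.DataFrame(np.vstack(prop_rows), index=sample_ids, columns=ct_names)
    return SyntheticCohort(beta, detp, pheno, props, effect_spec)


def _logit_noise_matrix(bulk, donor_re, rng, noise_sd):
    z = logit(np.clip(bulk, _EPS, 1 - _EPS))
    if donor_re is not None:
        z = z + donor_re
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=bulk.shape)
    return expit(z)


# ---------------------------------------------------------------------------
# sorted-nuclei fraction study
# ---------------------------------------------------------------------------

@dataclass
class SortedFractionStudy:
    """Per-fraction beta matrices ("total" mixture plus each purified
    population) with donor group labels (low/high tau pathology)."""
    fractions: dict
    labels: pd.DataFrame
    true_proportions: pd.DataFrame
    effect_spec: EffectSpec | None = None


def make_sorted_fraction_study(profiles, n_low=15, n_high=13, effect_spec=None,
                               base_proportions=None,
                               proportion_concentration=150.0, noise_sd=0.1,
                               low_stages=(0, 1, 2), high_stages=(5, 6),
                               seed=None):
    """Simulate a purified-nuclei study of low vs high pathology donors.

    Emits one beta matrix per fraction: each purified population carries
    its cell type's signal at full magnitude, while "total" (analogous to
    bulk cortex) is the proportion-weighted mixture, so cell-confined
    effects appear attenuated by the cell's mean proportion.
    """
    if n_low < 2 or n_high < 2:
        raise ValueError("need at least 2 donors per group")
    if base_proportions is None:
        base_proportions = DEFAULT_BASE_PROPORTIONS
    rng = _rng(seed)
    n = n_low + n_high
    donors = [f"S{i:03d}" for i in range(n)]
    group = np.array(["low"] * n_low + ["high"] * n_high)
    braak = np.concatenate([
        rng.choice(low_stages, size=n_low),
        rng.choice(high_stages, size=n_high)]).astype(float)
    age = np.clip(rng.normal(80, 8, size=n), 61, 101).round(1)
    sex = np.where(rng.uniform(size=n) < 0.5, "M", "F")
    batch = rng.integers(1, 4, size=n)

    ct_names, pi = _draw_proportions(rng, n, base_proportions,
                                     proportion_concentration)
    background = _background_profile(profiles)
    n_probes = profiles.n_probes
    probe_index = {p: i for i, p in enumerate(profiles.probe_ids)}

    # probes x celltypes x donors cell-level methylation
    cell_beta = np.repeat(profiles.mean_beta[:, :, None], n, axis=2)
    if effect_spec is not None:
        rows = np.array([probe_index[p] for p in effect_spec.target_probes])
        tc = profiles.celltype_names.index(effect_spec.target_celltype)
        if effect_spec.driving_measure != "braak_nft":
            raise ValueError("sorted study drives effects with braak_nft")
        cell_beta[rows[:, None], tc, np.arange(n)[None, :]] += np.outer(
            effect_spec.signed_effect / 100.0, braak)
    cell_beta = np.clip(cell_beta, 0.0, 1.0)

    fractions = {}
    total = np.einsum("pcd,dc->pd", cell_beta, pi) + np.outer(
        background, 1.0 - pi.sum(axis=1))
    fractions["total"] = pd.DataFrame(
        _logit_normal_noise(total, noise_sd, rng) if noise_sd > 0 else total,
        index=profiles.probe_ids, columns=[f"{d}_total" for d in donors])
    for c, name in enumerate(ct_names):
        mat = cell_beta[:, c, :]
        fractions[name] = pd.DataFrame(
            _logit_normal_noise(mat, noise_sd, rng) if noise_sd > 0 else mat,
            index=profiles.probe_ids, columns=[f"{d}_{name}" for d in donors])

    labels = pd.DataFrame({
        "donor_id": donors, "group": group, "braak_nft": braak,
        "age": age, "sex": sex, "batch": batch,
    }, index=pd.Index(donors, name="donor_id")).reset_index(drop=True).set_index("donor_id")
    props = pd.DataFrame(pi, index=donors, columns=ct_names)
    return SortedFractionStudy(fractions, labels, props, effect_spec)
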