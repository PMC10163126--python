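"""Synthetic donor cohorts with the statistical structure of islet
T cell infiltration data.

Each donor group is described by a :class:`GroupProfile` holding the
group-level summaries the generator is calibrated to reproduce: islets per
donor, the lognormal islet-area law, the fraction of islets infiltrated by
at least one CD3+ cell, the conditional probability of high infiltration
(>= 6 cells given >= 1), the donor-pooled CD3+ density (sum of counts over
sum of areas), the CD8+ fraction among CD3+ cells, the ICI fraction, the
exocrine density, and inter-donor heterogeneity.

Per-islet CD3+ counts follow a zero-inflated, zero-truncated negative
binomial law.  The infiltration probability of an islet depends on donor
(logit-normal random effect) and on islet size (logistic slope in
standardised log-area); the slope is calibrated so that the pooled Spearman
correlation between count and area matches the profile target.  Given
infiltration, the count is zero-truncated negative binomial with mean and
dispersion solved so that the expected pooled density and P(>=6 | >=1) hit
their targets exactly under the area law.  All calibration integrals use
Gauss-Hermite quadrature; nothing is fitted to realised cohorts.

Donor random effects are drawn by Latin-hypercube stratification of the
normal quantiles: each donor's effect is still exactly N(0, sigma) marginally,
but a small cohort covers the donor distribution evenly instead of clumping
by chance, so realised group means sit close to the calibration targets at
realistic cohort sizes (8-15 donors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .records import DonorRecord, Group, InsulinStatus, IsletRecord

__all__ = [
    "GroupProfile",
    "CohortProfile",
    "CalibrationError",
    "CountLaw",
    "CalibratedGroup",
    "default_study_profile",
    "calibrate_counts",
    "generate_cohort",
]

# Gauss-Hermite nodes/weights for E[f(Z)], Z ~ N(0,1)
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(40)
_GH_W = _GH_W / _GH_W.sum()

#: high-infiltration cut: counts >= 6 are HIGH
_HIGH = 6


class CalibrationError(ValueError):
    """The profile's targets cannot be met jointly; the message names the
    binding constraint."""


@dataclass
class GroupProfile:
    """Generator parameters for one donor group.

    Probabilities are proportions in [0, 1]; densities are CD3+ cells/mm^2;
    areas are mm^2 (arithmetic means of lognormal laws).
    """

    n_donors: int
    islets_per_donor_mean: float
    islet_area_mean_mm2: float
    p_infiltrated: float
    p_high_given_infiltrated: float
    target_pooled_density: float
    cd8pos_fraction: float
    exocrine_density: float
    islet_area_logsd: float = 0.8
    p_ici: float = 1.0
    count_area_corr: float = 0.35
    donor_sd_logit: float = 0.5
    exocrine_area_mean_mm2: float = 100.0
    exocrine_area_logsd: float = 0.25
    exocrine_density_logsd: float = 0.3
    # ICI/IDI contrast (type 1 diabetic donors): when the ratios are set,
    # ICI and IDI islets get separate calibrated count laws whose mixture
    # still meets the overall group targets.
    ici_idi_p_inf_ratio: float | None = None
    ici_idi_density_ratio: float | None = None
    ici_area_mean_mm2: float | None = None
    idi_area_mean_mm2: float | None = None
    # cellularity: one cell per this much area sets n_cells from islet area
    per_cell_area_mm2: float = 4e-6
    # fraction of detected objects that are sub-threshold artefacts, below
    # the >=30-cell inclusion filter; they exercise the filter downstream
    p_small_islet: float = 0.03
    small_islet_area_mean_mm2: float = 6e-5
    small_islet_area_logsd: float = 0.4

    @property
    def islet_area_logmean(self) -> float:
        """Log-scale mean of the islet-area lognormal."""
        return math.log(self.islet_area_mean_mm2) - self.islet_area_logsd**2 / 2

    def violations(self) -> list[str]:
        errs = []
        for name in ("p_infiltrated", "p_high_given_infiltrated", "cd8pos_fraction",
                     "p_ici", "p_small_islet"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                errs.append(f"{name} must be in [0,1], got {v}")
        for name in ("islet_area_mean_mm2", "exocrine_density", "exocrine_area_mean_mm2",
                     "islets_per_donor_mean", "per_cell_area_mm2"):
            if not getattr(self, name) > 0:
                errs.append(f"{name} must be > 0")
        if not -1 <= self.count_area_corr <= 1:
            errs.append("count_area_corr must be in [-1,1]")
        if self.donor_sd_logit < 0:
            errs.append("donor_sd_logit must be >= 0")
        return errs

    def validate(self) -> "GroupProfile":
        errs = self.violations()
        if errs:
            raise CalibrationError("; ".join(errs))
        return self


@dataclass
class CohortProfile:
    """Profiles for every donor group plus the master seed."""

    groups: dict[Group, GroupProfile]
    seed: int = 0

    def validate(self) -> "CohortProfile":
        if not self.groups:
            raise ValueError("CohortProfile.groups must be non-empty")
        for g in self.groups.values():
            g.validate()
        return self


def default_study_profile() -> CohortProfile:
    """Cohort profile calibrated to the published group-level summaries.

    Fifteen non-diabetic donors (~341 islets each), eight double
    autoantibody-positive donors (~192) and ten recent-onset type 1 diabetic
    donors (~201).  Targets: LOW/HIGH infiltration fractions of 17.1%/0.4%
    (ND), 33%/4.5% (AAb+) and 32.5%/8.2% (T1D); pooled islet CD3+ densities
    17.3 / 55.4 / 74.8 cells/mm^2; exocrine densities 34.8 / 55.4 / 85.4
    cells/mm^2; mean islet area 0.019 mm^2 (ND) or 0.021 mm^2 (AAb+);
    40.5% insulin-containing islets in T1D with infiltration extent 55.4%
    (ICI) vs 34% (IDI) and mean areas 0.027 vs 0.014 mm^2.  CD8+ fractions
    derive from the exocrine CD3+CD8-:CD3+CD8+ ratios (0.36/0.30/0.45).
    """
    nd = GroupProfile(
        n_donors=15,
        islets_per_donor_mean=341.0,
        islet_area_mean_mm2=0.019,
        p_infiltrated=(17.1 + 0.4) / 100,
        p_high_given_infiltrated=0.4 / 17.5,
        target_pooled_density=17.3,
        cd8pos_fraction=1 / 1.36,       # CD8-:CD8+ ratio 0.36
        exocrine_density=34.8,
        p_ici=1.0,
    )
    aab = GroupProfile(
        n_donors=8,
        islets_per_donor_mean=192.0,
        islet_area_mean_mm2=0.021,
        p_infiltrated=(33.0 + 4.5) / 100,
        p_high_given_infiltrated=4.5 / 37.5,
        target_pooled_density=55.4,
        cd8pos_fraction=1 / 1.30,       # ratio 0.30
        exocrine_density=55.4,
        p_ici=0.935,
    )
    t1d = GroupProfile(
        n_donors=10,
        islets_per_donor_mean=201.0,
        islet_area_mean_mm2=0.021,
        p_infiltrated=(32.5 + 8.2) / 100,
        p_high_given_infiltrated=8.2 / 40.7,
        target_pooled_density=74.8,
        cd8pos_fraction=1 / 1.45,       # ratio 0.45
        exocrine_density=85.4,
        p_ici=0.405,
        ici_idi_p_inf_ratio=55.4 / 34.0,
        ici_idi_density_ratio=1.525,    # pooled CD3+ density 52.5% higher in ICIs
        ici_area_mean_mm2=0.027,
        idi_area_mean_mm2=0.014,
    )
    return CohortProfile(groups={Group.ND: nd, Group.AAB2: aab, Group.T1D: t1d})


def save_profile(profile: CohortProfile, path) -> None:
    """Write a cohort profile as a human-editable YAML file (one section per
    group)."""
    import yaml
    from dataclasses import asdict

    doc = {"seed": profile.seed,
           "groups": {g.value: asdict(gp) for g, gp in profile.groups.items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_profile(path) -> CohortProfile:
    """Read a cohort profile written by :func:`save_profile`."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    groups = {
        Group(name): GroupProfile(**params)
        for name, params in (doc.get("groups") or {}).items()
    }
    return CohortProfile(groups=groups, seed=int(doc.get("seed", 0))).validate()


# --------------------------------------------------------------------------
# calibration


@dataclass
class CountLaw:
    """Calibrated per-islet CD3+ count law for one insulin-status stratum.

    Infiltration: P(count >= 1 | donor effect u, islet log-area z) =
    expit(alpha + sigma_d * u + beta * z) with z the standardised log-area.
    Given infiltration, count ~ NB(mean mu_base, size k) truncated to >= 1.
    Degenerate all-zero laws have ``alpha = -inf``.
    """

    alpha: float
    beta: float
    mu_base: float
    k: float
    area_logmean: float
    area_logsd: float
    sigma_d: float
    p_infiltrated: float
    pooled_density: float

    @property
    def area_mean(self) -> float:
        return math.exp(self.area_logmean + self.area_logsd**2 / 2)


@dataclass
class CalibratedGroup:
    """Calibrated laws per insulin-status stratum for a donor group."""

    profile: GroupProfile
    beta: float
    laws: dict[InsulinStatus, CountLaw]
    achieved_corr: float

    def law_for(self, status: InsulinStatus) -> CountLaw:
        if status in self.laws:
            return self.laws[status]
        return self.laws[InsulinStatus.UNKNOWN]


#: log-spaced dispersion grid bracketing the k solve; P(>=6 | >=1) at fixed
#: truncated mean is not monotone in k (interior maximum), so roots are
#: located on a grid first and refined inside one bracket.
_K_GRID = np.exp(np.linspace(math.log(5e-3), math.log(1e3), 25))


def _mu_for_truncated_mean(m_pos: float, k: float) -> float:
    """NB mean mu whose zero-truncated mean equals ``m_pos`` (> 1)."""
    g = lambda lm: math.exp(lm) / (1.0 - (k / (k + math.exp(lm))) ** k) - m_pos
    return math.exp(optimize.brentq(g, math.log(1e-10), math.log(1e8), xtol=1e-13))


def _ph_at(m_pos: float, k: float) -> float:
    """P(X >= 6 | X >= 1) of the zero-truncated NB with truncated mean m_pos."""
    mu = _mu_for_truncated_mean(m_pos, k)
    p = k / (k + mu)
    p0 = p**k
    return float(stats.nbinom.sf(_HIGH - 1, k, p) / (1.0 - p0))


def _ph_range(m_pos: float) -> tuple[float, float]:
    vals = [_ph_at(m_pos, k) for k in _K_GRID]
    return min(vals), max(vals)


def _solve_k(m_pos: float, ph_target: float) -> float:
    """Dispersion k with P(>=6|>=1) = ph_target at truncated mean m_pos.

    Scans the k grid and refines within the first bracketing interval
    (smallest k), which makes the choice deterministic when several roots
    exist.
    """
    vals = np.array([_ph_at(m_pos, k) for k in _K_GRID])
    diffs = vals - ph_target
    hit = np.nonzero(np.abs(diffs) < 1e-12)[0]
    if hit.size:
        return float(_K_GRID[hit[0]])
    sign = np.sign(diffs)
    brackets = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if brackets.size == 0:
        lo, hi = vals.min(), vals.max()
        raise CalibrationError(
            f"infeasible targets: P(>={_HIGH}|>=1) = {ph_target:.4g} outside the "
            f"achievable range [{lo:.4g}, {hi:.4g}] at mean count per "
            f"infiltrated islet {m_pos:.4g}"
        )
    i = int(brackets[0])
    return optimize.brentq(
        lambda k: _ph_at(m_pos, k) - ph_target, _K_GRID[i], _K_GRID[i + 1], xtol=1e-10
    )


def _solve_stratum(
    p_inf: float,
    p_high_t: float,
    density: float,
    area_logmean: float,
    area_logsd: float,
    sigma_d: float,
    beta: float,
) -> CountLaw:
    """Solve (alpha, mu_base, k) for one stratum's targets.

    The logit intercept alpha matches the marginal infiltration probability
    under Gauss-Hermite quadrature over log-area and donor effect.  Because
    the positive-count mean does not depend on area, the pooled-density
    constraint reduces to a fixed truncated mean
    ``m_pos = density * mean_area / p_inf``; (mu_base, k) then match that
    mean and P(>=6 | >=1) jointly.
    """
    abar = math.exp(area_logmean + area_logsd**2 / 2)
    if p_inf == 0:
        if density > 0:
            raise CalibrationError(
                "infeasible targets: p_infiltrated = 0 but target_pooled_density > 0"
            )
        return CountLaw(-math.inf, beta, 0.0, 1.0, area_logmean, area_logsd,
                        sigma_d, 0.0, 0.0)
    if density <= 0:
        raise CalibrationError(
            "infeasible targets: p_infiltrated > 0 requires target_pooled_density > 0"
        )
    m_pos = density * abar / p_inf
    if m_pos <= 1.0:
        raise CalibrationError(
            "infeasible targets: implied mean count per infiltrated islet "
            f"{m_pos:.4g} <= 1 (density too low for p_infiltrated)"
        )

    z = _GH_X

    def f_alpha(alpha):
        grid = expit(alpha + sigma_d * _GH_X[:, None] + beta * z[None, :])
        return float(_GH_W @ grid @ _GH_W) - p_inf

    if p_inf >= 1.0:
        alpha = math.inf          # saturated: every islet infiltrated
    else:
        alpha = optimize.brentq(f_alpha, -40.0, 40.0, xtol=1e-12)
    k = _solve_k(m_pos, p_high_t)
    mu_base = _mu_for_truncated_mean(m_pos, k)
    return CountLaw(alpha, beta, mu_base, k, area_logmean, area_logsd,
                    sigma_d, p_inf, density)


def _stratum_targets(profile: GroupProfile):
    """Per-insulin-status (weight, p_inf, density, p_high, area_logmean).

    With an ICI/IDI contrast, stratum infiltration probabilities and pooled
    densities are solved so the mixture reproduces the overall group targets
    at the requested ICI:IDI ratios.  Status-specific area means are rescaled
    to preserve the overall mean islet area (their ratio is kept), since the
    group-level density targets are defined against that overall area law.
    Per-stratum high-infiltration probabilities are chosen within their
    feasible bands so the overall fraction of >= 6-cell islets is exact.
    """
    p = profile
    if p.ici_idi_p_inf_ratio is None or not 0 < p.p_ici < 1:
        logmean = p.islet_area_logmean
        return {
            InsulinStatus.UNKNOWN: (
                1.0, p.p_infiltrated, p.target_pooled_density,
                p.p_high_given_infiltrated, logmean,
            )
        }
    w_i, w_d = p.p_ici, 1.0 - p.p_ici
    r_p = p.ici_idi_p_inf_ratio
    r_d = p.ici_idi_density_ratio if p.ici_idi_density_ratio is not None else r_p
    a_i = p.ici_area_mean_mm2 or p.islet_area_mean_mm2
    a_d = p.idi_area_mean_mm2 or p.islet_area_mean_mm2
    # keep the ICI:IDI area ratio but preserve the overall mean islet area
    scale = p.islet_area_mean_mm2 / (w_i * a_i + w_d * a_d)
    a_i, a_d = a_i * scale, a_d * scale
    p_idi = p.p_infiltrated / (w_i * r_p + w_d)
    p_ici = r_p * p_idi
    if p_ici > 1:
        raise CalibrationError("infeasible targets: implied ICI p_infiltrated > 1")
    # overall pooled density is count-sum over area-sum across both strata
    d_idi = p.target_pooled_density * (w_i * a_i + w_d * a_d) / (w_i * r_d * a_i + w_d * a_d)
    d_ici = r_d * d_idi
    ph_i, ph_d = _split_ph(
        p.p_infiltrated * p.p_high_given_infiltrated,
        [(w_i * p_ici, d_ici * a_i / p_ici), (w_d * p_idi, d_idi * a_d / p_idi)],
    )
    s2 = p.islet_area_logsd**2 / 2
    return {
        InsulinStatus.ICI: (w_i, p_ici, d_ici, ph_i, math.log(a_i) - s2),
        InsulinStatus.IDI: (w_d, p_idi, d_idi, ph_d, math.log(a_d) - s2),
    }


def _split_ph(overall_high: float, strata: list[tuple[float, float]]) -> list[float]:
    """Per-stratum P(>=6 | >=1) targets meeting the overall >= 6 fraction.

    ``strata`` holds (weight x p_infiltrated, truncated mean) per stratum.
    Each stratum's probability is interpolated inside its feasible band
    (narrowed a hair to keep the k solve bracketed) by a common position t,
    solved so the weighted sum equals ``overall_high``; t is unique because
    the sum is increasing in t.
    """
    bands = []
    for wp, m_pos in strata:
        lo, hi = _ph_range(m_pos)
        margin = 1e-4 * (hi - lo)
        bands.append((lo + margin, hi - margin))

    def total(t):
        return sum(wp * (lo + t * (hi - lo))
                   for (wp, _), (lo, hi) in zip(strata, bands))

    if not total(0.0) <= overall_high <= total(1.0):
        raise CalibrationError(
            "infeasible targets: overall high-infiltration fraction "
            f"{overall_high:.4g} outside the achievable range "
            f"[{total(0.0):.4g}, {total(1.0):.4g}] for the ICI/IDI mixture"
        )
    t = optimize.brentq(lambda x: total(x) - overall_high, 0.0, 1.0, xtol=1e-12)
    return [lo + t * (hi - lo) for lo, hi in bands]


def _simulated_corr(laws, strata, profile, beta, n, seed) -> float:
    """Spearman corr(count, area) over a pooled simulated stratum mixture."""
    rng = np.random.default_rng(seed)
    areas = np.empty(n)
    counts = np.empty(n)
    pos = 0
    items = list(strata.items())
    weights = np.array([w for w, *_ in strata.values()])
    ns = rng.multinomial(n, weights / weights.sum())
    for (status, _), m in zip(items, ns):
        law = laws[status]
        u = rng.standard_normal(m)          # donor effect folded per-islet
        z = rng.standard_normal(m)
        a = np.exp(law.area_logmean + law.area_logsd * z)
        c = _draw_counts(law, z, u, rng)
        areas[pos:pos + m] = a
        counts[pos:pos + m] = c
        pos += m
    if np.all(counts == counts[0]):
        return 0.0
    return float(stats.spearmanr(counts[:pos], areas[:pos]).statistic)


def _draw_counts(law: CountLaw, z: np.ndarray, u: np.ndarray, rng) -> np.ndarray:
    """Sample per-islet CD3+ counts given standardised log-areas z and donor
    effects u, by inverse-CDF sampling of the zero-truncated NB."""
    n = z.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    if law.alpha == -math.inf:
        return counts
    p_inf = expit(law.alpha + law.sigma_d * u + law.beta * z)
    infil = rng.random(n) < p_inf
    idx = np.nonzero(infil)[0]
    if idx.size:
        mu = law.mu_base
        pnb = law.k / (law.k + mu)
        p0 = pnb**law.k
        uu = p0 + rng.random(idx.size) * (1.0 - p0)
        c = stats.nbinom.ppf(np.minimum(uu, 1.0 - 1e-14), law.k, pnb)
        counts[idx] = np.maximum(c.astype(np.int64), 1)
    return counts


#: memo of calibrations by profile parameter tuple (calibration is pure)
_CALIB_CACHE: dict[tuple, "CalibratedGroup"] = {}


def calibrate_counts(profile: GroupProfile, corr_sim_n: int = 60_000,
                     corr_tol: float = 0.02) -> CalibratedGroup:
    """Calibrate the zero-inflated count law(s) for one group profile.

    Solves, per insulin-status stratum, the logit intercept, truncated-NB
    mean and dispersion matching the marginal infiltration probability, the
    pooled density and P(>=6 | >=1); then bisects the log-area slope beta so
    the pooled count-area Spearman correlation (estimated on a fixed-seed
    simulation of ``corr_sim_n`` islets) meets ``count_area_corr``.
    """
    profile.validate()
    from dataclasses import astuple

    cache_key = (astuple(profile), corr_sim_n, corr_tol)
    if cache_key in _CALIB_CACHE:
        return _CALIB_CACHE[cache_key]
    strata = _stratum_targets(profile)

    def laws_at(beta):
        return {
            status: _solve_stratum(p_inf, ph, dens, logmean,
                                   profile.islet_area_logsd,
                                   profile.donor_sd_logit, beta)
            for status, (w, p_inf, dens, ph, logmean) in strata.items()
        }

    target = profile.count_area_corr
    if target == 0 or profile.p_infiltrated == 0:
        laws = laws_at(0.0)
        rho = _simulated_corr(laws, strata, profile, 0.0, corr_sim_n, seed=20230)
        out = CalibratedGroup(profile, 0.0, laws, rho)
        _CALIB_CACHE[cache_key] = out
        return out

    def rho_of(beta):
        return _simulated_corr(laws_at(beta), strata, profile, beta, corr_sim_n,
                               seed=20230)

    lo, hi = 0.0, 4.0
    r_lo, r_hi = rho_of(lo), rho_of(hi)
    if not (min(r_lo, r_hi) - corr_tol <= target <= max(r_lo, r_hi) + corr_tol):
        raise CalibrationError(
            f"infeasible targets: count_area_corr {target} outside achievable "
            f"range [{r_lo:.3f}, {r_hi:.3f}]"
        )
    if target <= r_lo:
        beta = lo
    elif target >= r_hi:
        beta = hi
    else:
        beta = optimize.brentq(lambda b: rho_of(b) - target, lo, hi, xtol=1e-3)
    laws = laws_at(beta)
    out = CalibratedGroup(profile, beta, laws, rho_of(beta))
    _CALIB_CACHE[cache_key] = out
    return out


# --------------------------------------------------------------------------
# generation


def _lhs_normal(n: int, rng) -> np.ndarray:
    """n Latin-hypercube-stratified standard normal draws (exact marginal)."""
    u = (rng.permutation(n) + rng.random(n)) / n
    return stats.norm.ppf(u)


def generate_cohort(profile: CohortProfile, seed: int | None = None) -> list[DonorRecord]:
    """Generate a full donor cohort from a calibrated profile.

    Reproducible given the seed: every donor draws from its own substream
    derived from (seed, group index, donor index), so cohorts are stable
    under changes in donor counts of other groups.
    """
    profile.validate()
    if seed is None:
        seed = profile.seed
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    donors: list[DonorRecord] = []
    for g_idx, (group, gp) in enumerate(profile.groups.items()):
        calib = calibrate_counts(gp)
        g_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1000 + g_idx]))
        u_donor = _lhs_normal(gp.n_donors, g_rng)        # infiltration effect
        v_donor = _lhs_normal(gp.n_donors, g_rng)        # exocrine effect
        for d_idx in range(gp.n_donors):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 1000 + g_idx, d_idx])
            )
            donor_id = f"{group.value}-{d_idx + 1:02d}"
            donors.append(
                _generate_donor(donor_id, group, gp, calib,
                                float(u_donor[d_idx]), float(v_donor[d_idx]), rng)
            )
    return donors


def _generate_donor(donor_id, group, gp: GroupProfile, calib: CalibratedGroup,
                    u: float, v: float, rng) -> DonorRecord:
    n_islets = int(rng.poisson(gp.islets_per_donor_mean))
    n_islets = max(n_islets, 1)
    small = rng.random(n_islets) < gp.p_small_islet
    if 0 < gp.p_ici < 1:
        ici = rng.random(n_islets) < gp.p_ici
        statuses = np.where(ici, InsulinStatus.ICI.value, InsulinStatus.IDI.value)
    elif gp.p_ici >= 1:
        statuses = np.full(n_islets, InsulinStatus.ICI.value)
    else:
        statuses = np.full(n_islets, InsulinStatus.IDI.value)

    areas = np.empty(n_islets)
    counts = np.zeros(n_islets, dtype=np.int64)
    zscores = np.empty(n_islets)
    small_logmean = (math.log(gp.small_islet_area_mean_mm2)
                     - gp.small_islet_area_logsd**2 / 2)
    for status in np.unique(statuses):
        law = calib.law_for(InsulinStatus(status))
        sel = np.nonzero(statuses == status)[0]
        z = rng.standard_normal(sel.size)
        a = np.exp(law.area_logmean + law.area_logsd * z)
        # sub-threshold artefact objects: tiny area, same count law at their
        # (very negative) standardised log-area
        sm = sel[small[sel]]
        if sm.size:
            z_sm = rng.standard_normal(sm.size)
            a_sm = np.exp(small_logmean + gp.small_islet_area_logsd * z_sm)
            a[small[sel]] = a_sm
            z[small[sel]] = (np.log(a_sm) - law.area_logmean) / law.area_logsd
        areas[sel] = a
        zscores[sel] = z
        counts[sel] = _draw_counts(law, z, np.full(sel.size, u), rng)

    n_cells = np.maximum(np.round(areas / gp.per_cell_area_mm2), 1).astype(np.int64)
    cd8pos = rng.binomial(counts, gp.cd8pos_fraction)

    islets = [
        IsletRecord(
            donor_id=donor_id,
            islet_id=f"{donor_id}-i{j + 1:04d}",
            area_mm2=float(areas[j]),
            n_cells=int(n_cells[j]),
            insulin_status=InsulinStatus(statuses[j]),
            cd3_count=int(counts[j]),
            cd3cd8pos_count=int(cd8pos[j]),
            cd3cd8neg_count=int(counts[j] - cd8pos[j]),
        )
        for j in range(n_islets)
    ]

    exo_logmean = math.log(gp.exocrine_area_mean_mm2) - gp.exocrine_area_logsd**2 / 2
    exo_area = float(np.exp(exo_logmean + gp.exocrine_area_logsd * rng.standard_normal()))
    dens = gp.exocrine_density * math.exp(
        gp.exocrine_density_logsd * v - gp.exocrine_density_logsd**2 / 2
    )
    exo_cd3 = int(rng.poisson(dens * exo_area))
    exo_pos = int(rng.binomial(exo_cd3, gp.cd8pos_fraction))

    endocrine = float(areas.sum())
    return DonorRecord(
        donor_id=donor_id,
        group=group,
        islets=islets,
        total_area_mm2=endocrine + exo_area,
        endocrine_area_mm2=endocrine,
        exocrine_cd3=exo_cd3,
        exocrine_cd3cd8pos=exo_pos,
        exocrine_cd3cd8neg=exo_cd3 - exo_pos,
    ).validate()
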