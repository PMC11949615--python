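"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The cohort this package was designed around (54 young adults, two fMRI scans,
rest / stop-signal-task / rest) is not publicly deposited, so every stage of
the pipeline is exercised on synthetic data that emulates its design:

* a stable per-subject FC "fingerprint": each subject's latent covariance is
  a shared low-rank base plus a subject-specific low-rank component plus a
  heterogeneous diagonal (guaranteed SPD);
* a task effect: the SST segment's covariance is displaced along a common
  low-rank task direction with a per-subject amplitude ``a_s``, while a
  fraction of the shared baseline structure is suppressed in proportion to
  the same amplitude (task-positive coupling appears, default-mode-like
  coupling weakens);
* lingering task structure: the post-task rest segments retain fractions
  ``(1 - g_s)`` (R2.1) and ``(1 - h_s)`` (R2.2, with ``h_s > g_s``) of the
  task component, so engaging reconfiguration scales with ``a_s``,
  disengaging with ``a_s * g_s`` and within-rest with ``a_s * (h_s - g_s)``
  — reproducing the engaging > disengaging > within-rest ordering;
* a scan effect: all scan-2 segments share a common low-rank offset;
* observation noise: each segment's time series is multivariate normal with
  covariance ``Sigma_segment + noise_sd^2 I``;
* covariate-driven reconfiguration differences: the engaging amplitude
  ``a_s = exp(eta)`` shrinks with recent drinking and male sex and grows with
  CES-D; the disengaging fraction ``g_s`` shrinks with positive family
  history (FHA) and grows with education and CES-D.

Covariates are drawn to match the cohort description: exact FHA-positive and
male counts, age/education/SSRT/CES-D moments, and four drinking measures
whose group means differ by FHA and whose first principal component carries
about 65% of their variance.

Ground truth for model-recovery testing is the *noise-free* pipeline: the
analysis (FC -> regularize -> Riemann-mean reference -> tangent projection ->
reconfiguration -> OLS) applied to the exact segment covariances (the
infinite-scan-length limit, observation-noise diagonal included).  The
resulting reconfiguration targets and OLS coefficients are stored in
:class:`GroundTruth` and are bit-reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import spd
from .connectivity import (
    SCAN_SEGMENTS,
    SEGMENTS,
    BoldTimeSeries,
    default_scheme,
    nominal_scan_volumes,
)
from .regression import prepare_design, fit_reconfig_model, PREDICTORS

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Cohort",
    "generate_covariates",
    "generate_cohort",
    "generate_spd",
]

#: cohort-description calibration targets: mean, sd per covariate
_AGE = (22.64, 1.62, 21.0, 26.0)  # mean, sd, clip lo, clip hi
_EDUCATION = (15.25, 1.20)
_CESD = (5.96, 5.09)
_SSRT = (238.0, 51.0)
_FHA_FRACTION = 23 / 54
_MALE_FRACTION_BY_FHA = {1: 9 / 23, 0: 16 / 31}

#: drinking measures by FHA group: (mean, sd)
_DRINKING = {
    1: {
        "audit": (10.26, 6.52),
        "drinking_days": (16.17, 8.02),
        "drinks_per_week": (12.27, 11.45),
        "drinks_per_drinking_day": (3.66, 1.92),
    },
    0: {
        "audit": (7.26, 3.92),
        "drinking_days": (10.54, 5.60),
        "drinks_per_week": (7.11, 4.91),
        "drinks_per_drinking_day": (3.67, 2.39),
    },
}

#: shared-factor loading giving the drinking PC1 about 65% of the variance
#: (equicorrelation rho with leading eigenvalue 1 + 3 rho = 4 * 0.65)
_DRINK_RHO = (4 * 0.65 - 1.0) / 3.0


@dataclass
class SyntheticConfig:
    """Generating conditions for a synthetic cohort.

    The defaults are the package's standard study conditions: cohort size 54,
    50 regions (332 supported), TR 1.2 s with the two-scan layout, moderate
    fingerprint / task / scan components, and covariate effects with the
    directions reported for this design (drinking and male sex reduce the
    engaging amplitude; FHA reduces, education and CES-D increase, the
    disengaging fraction).  ``seed`` is mandatory — there is no silent
    nondeterminism.
    """

    seed: int
    n_subjects: int = 54
    n_regions: int = 50
    tr_seconds: float = 1.2
    fingerprint_strength: float = 3.0
    task_effect: float = 0.9
    task_suppression: float = 0.3
    scan_effect: float = 0.3
    noise_sd: float = 0.4
    beta_drink_engage: float = 0.35
    beta_sex: float = 0.30
    beta_cesd: float = 0.22
    beta_fha_disengage: float = 0.55
    beta_edu: float = 0.30
    amplitude_noise: float = 0.25
    disengage_base: float = 0.65
    rest_decay: float = 0.25
    shared_rank: int = 6
    fingerprint_rank: int = 3
    task_rank: int = 2
    scan_rank: int = 2
    base_diag_range: tuple = (0.5, 1.5)
    target_lam: float = 0.001

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "fingerprint_strength", "task_effect", "task_suppression",
            "scan_effect", "noise_sd",
            "beta_drink_engage", "beta_sex", "beta_cesd",
            "beta_fha_disengage", "beta_edu", "amplitude_noise",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        if not 0.0 < self.disengage_base < 1.0:
            raise ValueError("disengage_base must lie in (0, 1)")
        if not 0.0 <= self.rest_decay <= 1.0:
            raise ValueError("rest_decay must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    subject_bases: list
    task_direction: np.ndarray
    scan_component: np.ndarray
    segment_covariances: dict
    engage_amplitude: np.ndarray
    disengage_fraction: np.ndarray
    rest_fraction: np.ndarray
    generating_betas: dict
    noise_free_reconfiguration: dict = field(default_factory=dict)
    true_coefficients: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """A generated cohort: time series, covariates, and ground truth."""

    time_series: dict
    covariates: pd.DataFrame
    ground_truth: GroundTruth
    config: SyntheticConfig

    @property
    def subject_order(self) -> list:
        return list(self.covariates.index)


def _subject_ids(n: int):
    width = max(2, len(str(n)))
    return [f"sub-{i + 1:0{width}d}" for i in range(n)]


def generate_covariates(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Draw a covariate table calibrated to the cohort description.

    Exactly ``round(n * 23/54)`` subjects are FHA positive and the male count
    follows the per-group fractions (25/54 overall).  Age is normal
    (22.64, 1.62^2) clipped to [21, 26]; education normal (15.25, 1.20^2);
    CES-D normal (5.96, 5.09^2) floored at 0; SSRT normal (238, 51^2).  The
    four drinking measures share a latent factor (so their first principal
    component explains about 65% of variance) and their group means are
    shifted by FHA status.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_pos = int(round(n * _FHA_FRACTION))
    fha = np.zeros(n, dtype=int)
    fha[:n_pos] = 1
    sex = np.zeros(n, dtype=int)
    for grp in (1, 0):
        idx = np.flatnonzero(fha == grp)
        n_male = int(round(idx.size * _MALE_FRACTION_BY_FHA[grp]))
        sex[idx[:n_male]] = 1
    perm = rng.permutation(n)
    fha, sex = fha[perm], sex[perm]

    mu, sd, lo, hi = _AGE
    age = np.clip(rng.normal(mu, sd, n), lo, hi)
    education = rng.normal(*_EDUCATION, n)
    cesd = np.maximum(rng.normal(*_CESD, n), 0.0)
    ssrt_ms = rng.normal(*_SSRT, n)

    factor = rng.normal(size=n)
    drink = {}
    for name in ("audit", "drinking_days", "drinks_per_week", "drinks_per_drinking_day"):
        eps = rng.normal(size=n)
        z = np.sqrt(_DRINK_RHO) * factor + np.sqrt(1 - _DRINK_RHO) * eps
        vals = np.empty(n)
        for grp in (0, 1):
            m, s = _DRINKING[grp][name]
            sel = fha == grp
            vals[sel] = m + s * z[sel]
        drink[name] = vals

    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "education": education,
            "ssrt": ssrt_ms,
            "cesd": cesd,
            **drink,
            "fha": fha,
        },
        index=pd.Index(_subject_ids(n), name="subject"),
    )


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    s = v.std(ddof=0)
    if s == 0.0:
        return np.zeros_like(v)
    return (v - v.mean()) / s


def _low_rank(rng, p: int, rank: int) -> np.ndarray:
    """Random PSD matrix with unit-scale diagonal: ``V V^T / rank``."""
    v = rng.normal(size=(p, rank))
    m = v @ v.T / rank
    return 0.5 * (m + m.T)


def _segment_covariances(config: SyntheticConfig, base, shared, c_scan, d_task, a, g, h):
    """Latent covariance of each segment for one subject.

    The task displacement ``a * (tau * D_task - mu * G_shared)`` adds
    task-positive coupling and suppresses part of the shared baseline
    structure; post-task rest retains fractions (1 - g) and (1 - h) of it.
    With ``mu * a <= 1`` every segment covariance is a sum of PSD components
    plus a positive diagonal, hence SPD.
    """
    displacement = config.task_effect * d_task - config.task_suppression * shared
    return {
        "R1.1": base,
        "R1.2": base,
        "SST": base + c_scan + a * displacement,
        "R2.1": base + c_scan + a * (1.0 - g) * displacement,
        "R2.2": base + c_scan + a * (1.0 - h) * displacement,
    }


def _cov_to_corr(c: np.ndarray) -> np.ndarray:
    d = 1.0 / np.sqrt(np.diag(c))
    r = c * np.outer(d, d)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _noise_free_targets(config: SyntheticConfig, gt: GroundTruth, design: pd.DataFrame,
                        subject_order):
    """Run the analysis pipeline on the exact segment covariances."""
    lam = config.target_lam
    sigma2 = config.noise_sd ** 2
    p = config.n_regions
    eye = sigma2 * np.eye(p)
    fcs = {
        seg: [
            spd.regularize(_cov_to_corr(gt.segment_covariances[sid][seg] + eye), lam)
            for sid in subject_order
        ]
        for seg in SEGMENTS
    }
    ref = spd.riemann_mean(fcs["R1.1"], label="noise-free-R1.1")
    tfcs = {seg: spd.tangent_project_many(fcs[seg], ref) for seg in SEGMENTS}
    from .identifiability import identifiability_matrix, reconfiguration_vector

    transitions = {
        "engaging": ("R1.2", "SST"),
        "disengaging": ("SST", "R2.1"),
        "within_rest": ("R2.1", "R2.2"),
    }
    for name, (a, b) in transitions.items():
        idm = identifiability_matrix(
            tfcs[a], tfcs[b], segment_pair=(a, b), subject_order=subject_order
        )
        vec = reconfiguration_vector(idm)
        gt.noise_free_reconfiguration[name] = vec.values
        res = fit_reconfig_model(vec.values, design, PREDICTORS)
        gt.true_coefficients[name] = res.params


def generate_cohort(config: SyntheticConfig, include_targets: bool = True) -> Cohort:
    """Generate a full synthetic cohort (both scans, all subjects).

    Returns time series with the complete scan layouts (calibration and
    transition volumes included, so the segmentation step runs exactly as it
    would on acquired data), the raw covariate table, and the ground truth.
    Bit-identical for identical ``(config)`` values.
    """
    rng = np.random.default_rng(config.seed)
    p, n = config.n_regions, config.n_subjects
    covariates = generate_covariates(config, rng)
    subject_order = list(covariates.index)
    design, _ = prepare_design(covariates)

    shared = _low_rank(rng, p, config.shared_rank)
    dlo, dhi = config.base_diag_range
    base_diag = np.diag(rng.uniform(dlo, dhi, size=p))
    d_task = _low_rank(rng, p, config.task_rank)
    c_scan = config.scan_effect * _low_rank(rng, p, config.scan_rank)

    eta_eng = (
        -config.beta_drink_engage * _zscore(design["drinking"])
        - config.beta_sex * _zscore(design["sex"])
        + config.beta_cesd * _zscore(design["cesd"])
        + config.amplitude_noise * rng.normal(size=n)
    )
    eta_dis = (
        -config.beta_fha_disengage * _zscore(design["fha"])
        + config.beta_edu * _zscore(design["education"])
        + config.beta_cesd * _zscore(design["cesd"])
        + config.amplitude_noise * rng.normal(size=n)
    )
    # amplitudes clipped so that mu * a stays below 1 (SPD guarantee above)
    a_hi = 3.0 if config.task_suppression == 0 else min(3.0, 0.95 / config.task_suppression)
    a_s = np.clip(np.exp(eta_eng - eta_eng.mean()), 1.0 / 3.0, a_hi)
    g_s = np.clip(config.disengage_base * np.exp(eta_dis - eta_dis.mean()), 0.05, 0.95)
    h_s = g_s + (1.0 - g_s) * config.rest_decay

    scheme = default_scheme(config.tr_seconds, *nominal_scan_volumes(config.tr_seconds))
    bases, seg_covs = [], {}
    time_series = {}
    sigma2 = config.noise_sd ** 2
    for i, sid in enumerate(subject_order):
        fp = config.fingerprint_strength * _low_rank(rng, p, config.fingerprint_rank)
        base = shared + fp + base_diag
        bases.append(base)
        covs = _segment_covariances(
            config, base, shared, c_scan, d_task, a_s[i], g_s[i], h_s[i]
        )
        seg_covs[sid] = covs
        chol = {}
        for seg, c in covs.items():
            obs = c + sigma2 * np.eye(p)
            w0 = np.linalg.eigvalsh(obs)[0]
            if w0 <= 0:
                raise ValueError(
                    f"latent covariance for {sid}/{seg} is not SPD "
                    f"(eigenvalue {w0:.3e}); reduce effect weights"
                )
            chol[seg] = np.linalg.cholesky(obs)
        for scan_id in ("scan1", "scan2"):
            blocks = []
            for label, start, stop in _volume_schedule(scheme, scan_id):
                L = chol[label]
                z = rng.standard_normal(size=(stop - start, p))
                blocks.append(z @ L.T)
            time_series[(sid, scan_id)] = BoldTimeSeries(
                np.vstack(blocks),
                tr_seconds=config.tr_seconds,
                subject_id=sid,
                scan_id=scan_id,
            )

    gt = GroundTruth(
        subject_bases=bases,
        task_direction=d_task,
        scan_component=c_scan,
        segment_covariances=seg_covs,
        engage_amplitude=a_s,
        disengage_fraction=g_s,
        rest_fraction=h_s,
        generating_betas={
            "beta_drink_engage": config.beta_drink_engage,
            "beta_sex": config.beta_sex,
            "beta_cesd": config.beta_cesd,
            "beta_fha_disengage": config.beta_fha_disengage,
            "beta_edu": config.beta_edu,
        },
    )
    if include_targets:
        _noise_free_targets(config, gt, design, subject_order)
    return Cohort(
        time_series=time_series, covariates=covariates, ground_truth=gt, config=config
    )


def _volume_schedule(scheme, scan_id):
    """Cover every volume of a scan with a segment label.

    Discarded calibration/transition volumes are sampled from the adjacent
    analysis segment's covariance (the scanner does not pause for them).
    """
    covered = sorted(
        [(a, b, lab) for lab, a, b in scheme.segments[scan_id]]
        + [(a, b, None) for sid, _, a, b in scheme.discarded if sid == scan_id]
    )
    out = []
    for k, (a, b, lab) in enumerate(covered):
        if lab is None:
            # borrow the following segment's label (or the previous at scan end)
            lab = covered[k + 1][2] if k + 1 < len(covered) else covered[k - 1][2]
        out.append((lab, a, b))
    return out


def generate_spd(p: int, n: int, condition_number_cap: float = 1e3, seed: int = 0):
    """Random SPD test matrices with condition number at most the cap.

    Eigenvalues are log-uniform in ``[cap^-1/2, cap^1/2]`` and eigenvectors
    come from the QR factorization of a Gaussian matrix; deterministic per
    seed.
    """
    if p < 1 or n < 1:
        raise ValueError("p and n must be >= 1")
    if condition_number_cap < 1:
        raise ValueError("condition_number_cap must be >= 1")
    rng = np.random.default_rng(seed)
    half = 0.5 * np.log(condition_number_cap)
    out = []
    for i in range(n):
        q, _ = np.linalg.qr(rng.normal(size=(p, p)))
        w = np.exp(rng.uniform(-half, half, size=p))
        m = (q * w) @ q.T
        out.append(spd.SPDMatrix(0.5 * (m + m.T), label=f"spd-{seed}-{i}"))
    return out
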