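"""Seeded synthetic COPD cohort: MEFV curves, paired CT volumes, profiles.

One latent severity variable ``s`` in [0, 1] drives every modality of a
synthetic subject:

* the descending-limb shape parameters (linear maps; at s=0 the limb is a
  uniform scoop with exponent 1.8, at s=1 a flattened limb, exponent 0.3,
  kinking to 3.4 at u* = 0.6 over a narrow transition),
* the CT densitometry targets (%LAA at -950 HU inspiration rises
  monotonically with s within group-consistent ranges),
* the ordered parenchymal-pattern profile (class weights shift from Normal
  towards Severe LAA as s grows).

Cohorts emulate a three-group structure (no / moderate / severe emphysema)
with group sizes 57/58/79 and per-group severity-score Gaussians of mean
(SD) 1.1 (1.5), 3.1 (2.6) and 6.8 (2.5): per subject a target score is
drawn from its group's Gaussian, inverted to ``s`` through the score map,
and the subject is synthesised from ``s``.  Everything is driven by one
``numpy`` Generator so a fixed seed reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import MEFVCurve, SpirometricIndices, spirometric_indices
from .densitometry import PairedCTStudy, emphysema_class
from .exceptions import DomainError
from .model import DELTA_REF, biomech_q, score_curve

#: atmospheric (barometric) pressure, kPa, for Boyle's-law gas compression
P_BAROMETRIC_KPA = 101.3

#: slope of theta_d - theta_p in s: max regime contrast is 3.1 at s=1
_DELTA_THETA_SLOPE = 3.1

GROUPS = ("NE", "ME", "SE")

#: group-consistent %LAA_-950insp ranges (kept clear of the 6/14 cut-offs)
LAA_RANGES = {"NE": (1.0, 5.5), "ME": (6.5, 13.5), "SE": (14.5, 35.0)}

REGIONS = ("LU", "LM", "LL", "RU", "RM", "RL")
PATTERN_CLASSES = ("normal", "mild_laa", "moderate_laa", "severe_laa")


@dataclass(frozen=True)
class PhenotypeParams:
    """True curve-shape parameters for one synthetic subject."""

    severity: float
    theta_p: float
    theta_d: float
    u_star: float
    w: float
    pef_l_s: float
    fvc_l: float
    rise_fraction: float

    @property
    def true_esi(self) -> float:
        return float(10.0 * np.clip((self.theta_d - self.theta_p) / DELTA_REF, 0.0, 1.0))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure: group sizes, score distributions, noise, seed."""

    n_ne: int = 57
    n_me: int = 58
    n_se: int = 79
    esi_group_means: tuple[float, float, float] = (1.1, 3.1, 6.8)
    esi_group_sds: tuple[float, float, float] = (1.5, 2.6, 2.5)
    noise_sd: float = 0.02
    n_samples: int = 200
    seed: int = 0
    fit_curves: bool = True

    def __post_init__(self):
        if min(self.n_ne, self.n_me, self.n_se) < 0:
            raise DomainError("group sizes must be non-negative")
        if min(self.esi_group_sds) <= 0:
            raise DomainError("group SDs must be positive")


@dataclass
class CohortRecord:
    """One synthetic subject across all modalities."""

    subject_id: str
    group: str
    severity: float
    esi_true: float
    esi_fit: float | None
    curve: MEFVCurve
    spiro: SpirometricIndices
    laa950_insp: float
    laa856_exp: float
    plda: float
    flda: float
    profile: "PatternProfile" = None  # set post-construction
    cluster: int = -1


def severity_to_params(s: float, rng: np.random.Generator | int | None = None) -> PhenotypeParams:
    """Map latent severity to curve-shape parameters and lung dimensions.

    The shape maps are deterministic in ``s``.  FVC is drawn from a
    log-normal with median 3.5 L (sigma 0.15): emphysema leaves the forced
    vital capacity largely intact.  PEF is log-normal with a
    severity-dependent median, 7 * exp(-0.65 s) L/s (sigma 0.15): absolute
    expiratory flows fall with worsening obstruction even though the
    *shape-only* severity score never sees the scale.  The -0.65 log-slope
    reproduces the roughly one-third drop in FEV1 observed between
    no-emphysema and severe-emphysema groups while FVC stays flat.
    """
    if not 0.0 <= s <= 1.0:
        raise DomainError(f"severity must lie in [0, 1], got {s}")
    rng = np.random.default_rng(rng)
    return PhenotypeParams(
        severity=float(s),
        theta_p=1.8 - 1.5 * s,
        theta_d=1.8 + 1.6 * s,
        u_star=0.6,
        w=0.25 - 0.18 * s,
        pef_l_s=float(rng.lognormal(np.log(7.0) - 0.65 * s, 0.15)),
        fvc_l=float(rng.lognormal(np.log(3.5), 0.15)),
        rise_fraction=float(rng.uniform(0.05, 0.12)),
    )


def severity_from_esi(esi: float) -> float:
    """Invert the score map: severity whose true ESI equals ``esi`` (clipped)."""
    return float(np.clip(esi * DELTA_REF / (10.0 * _DELTA_THETA_SLOPE), 0.0, 1.0))


def generate_curve(params: PhenotypeParams, noise_sd: float = 0.0,
                   n_samples: int = 200,
                   rng: np.random.Generator | int | None = None) -> MEFVCurve:
    """Forward-simulate an MEFV curve from phenotype parameters.

    The ascending limb rises linearly over ``rise_fraction * FVC``; the
    descending limb evaluates the two-regime model on the volume grid.
    Gaussian flow noise (SD ``noise_sd * PEF``) is added and clipped at
    zero; the first and last samples are pinned to zero flow so the trace
    starts at rest and is carried to completion.
    """
    if n_samples < 30:
        raise DomainError("n_samples must be >= 30")
    rng = np.random.default_rng(rng)
    v_pef = params.rise_fraction * params.fvc_l
    n_asc = max(3, int(round(n_samples * params.rise_fraction)))
    n_desc = n_samples - n_asc
    v_asc = np.linspace(0.0, v_pef, n_asc + 1)[:-1]
    f_asc = params.pef_l_s * v_asc / v_pef
    v_desc = np.linspace(v_pef, params.fvc_l, n_desc)
    u = (params.fvc_l - v_desc) / (params.fvc_l - v_pef)
    f_desc = params.pef_l_s * biomech_q(u, params.theta_p, params.theta_d,
                                        params.u_star, params.w)
    v = np.concatenate([v_asc, v_desc])
    f = np.concatenate([f_asc, f_desc])
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd * params.pef_l_s, size=f.size)
        f = np.clip(f, 0.0, None)
    f[0] = 0.0
    f[-1] = 0.0
    return MEFVCurve(volume_l=v, flow_l_s=f)


def effort_profile(u, palv_kpa: float):
    """Alveolar-pressure profile along the descending limb.

    Maximal near total lung capacity (u = 1) and declining smoothly to zero
    at end-expiration: p(u) = palv * sin(pi * u / 2).  Expiratory driving
    pressure is greatest at high-to-mid lung volumes and its decline toward
    low volumes is what releases the compressed gas.
    """
    return palv_kpa * np.sin(0.5 * np.pi * np.asarray(u, dtype=float))


def apply_gas_compression(curve: MEFVCurve, tgv_l: float, palv_kpa: float) -> MEFVCurve:
    """Re-plot a curve on the plethysmographic (thoracic) volume axis.

    Under expiratory effort the thoracic gas is compressed by Boyle's law,
    so the thoracic volume change exceeds the volume expired at the mouth:
    V_pleth = V + dV(u) with dV(u) = TGV * p(u) / (P_B + p(u)).  Flow is
    unchanged.  Because compression is largest at high lung volumes and
    decays towards end-expiration, the high-volume portion of the curve is
    compressed along the volume axis — the plethysmographic curve descends
    more steeply where the mouth-volume curve of an emphysematous subject
    looks flat.
    """
    if tgv_l <= 0:
        raise DomainError("thoracic gas volume must be positive")
    if palv_kpa < 0:
        raise DomainError("peak alveolar pressure must be non-negative")
    if palv_kpa == 0:
        return curve
    v = curve.volume_l
    i0 = curve.pef_index
    v_end = v[-1]
    span = v_end - v[i0]
    u = np.clip((v_end - v) / span, 0.0, 1.0) if span > 0 else np.ones_like(v)
    p = effort_profile(u, palv_kpa)
    dv = tgv_l * p / (P_BAROMETRIC_KPA + p)
    return MEFVCurve(volume_l=v + dv, flow_l_s=curve.flow_l_s.copy())


def compression_shift(tgv_l: float, palv_kpa: float) -> float:
    """Boyle's-law volume shift at the effort-profile peak (litres)."""
    return tgv_l * palv_kpa / (P_BAROMETRIC_KPA + palv_kpa)


def generate_paired_ct(dims: tuple[int, int, int], targets: dict,
                       rng: np.random.Generator | int | None = None) -> PairedCTStudy:
    """Synthesise an aligned inspiratory/expiratory HU pair hitting targets.

    ``targets`` carries percentages ``laa950_insp``, ``plda`` and ``flda``.
    Exact voxel counts per response-map class are assigned (rounded to the
    nearest voxel) and HU values are sampled uniformly within
    class-consistent ranges, e.g. persistent low-density voxels draw
    inspiratory HU from [-1000, -951] and expiratory HU from [-1000, -857].
    The mask covers the whole grid.
    """
    laa = float(targets["laa950_insp"])
    plda = float(targets["plda"])
    flda = float(targets["flda"])
    if not (0 <= plda <= laa <= 100) or flda < 0:
        raise DomainError("need 0 <= %pLDA <= %LAA_insp <= 100 and %fLDA >= 0")
    if laa + flda > 100:
        raise DomainError("%LAA_insp + %fLDA cannot exceed 100")
    rng = np.random.default_rng(rng)
    n = int(np.prod(dims))
    n_laa = int(round(laa * n / 100.0))
    n_plda = int(round(plda * n / 100.0))
    n_plda = min(n_plda, n_laa)
    n_other = n_laa - n_plda
    n_flda = int(round(flda * n / 100.0))
    n_normal = n - n_laa - n_flda
    if n_normal < 0:
        raise DomainError("targets leave no room for Normal voxels")

    insp = np.empty(n)
    exp_ = np.empty(n)
    # class order: pLDA, Other, fLDA, Normal
    counts = (n_plda, n_other, n_flda, n_normal)
    insp_ranges = ((-1000, -951), (-1000, -951), (-950, -700), (-950, -600))
    exp_ranges = ((-1000, -857), (-856, -600), (-1000, -857), (-856, -600))
    start = 0
    for cnt, (ilo, ihi), (elo, ehi) in zip(counts, insp_ranges, exp_ranges):
        sl = slice(start, start + cnt)
        insp[sl] = rng.uniform(ilo, ihi, cnt)
        exp_[sl] = rng.uniform(elo, ehi, cnt)
        start += cnt
    perm = rng.permutation(n)
    insp = insp[perm].reshape(dims)
    exp_ = exp_[perm].reshape(dims)
    mask = np.ones(dims, dtype=bool)
    return PairedCTStudy(insp_hu=insp, exp_hu=exp_, mask=mask)


def pattern_weights(s: float) -> np.ndarray:
    """Ordered-class weights at severity ``s``: discretised Beta(1+4s, 5-4s).

    The Beta density over [0, 1] is integrated over four equal bins, one per
    ordered class (Normal, Mild LAA, Moderate LAA, Severe LAA); as ``s``
    grows the mass migrates from Normal towards Severe LAA.
    """
    from scipy.stats import beta

    edges = np.linspace(0.0, 1.0, 5)
    cdf = beta.cdf(edges, 1.0 + 4.0 * s, 5.0 - 4.0 * s)
    w = np.diff(cdf)
    return w / w.sum()


def generate_profile(s: float, rng: np.random.Generator | int | None = None):
    """Six-region ordered-pattern profile for severity ``s``.

    Each region perturbs the subject severity by Gaussian noise (SD 0.05)
    before discretising, so regional heterogeneity is mild but present;
    region volume weights are near-uniform draws renormalised to 1.
    """
    from .clustering import PatternProfile

    rng = np.random.default_rng(rng)
    fractions = np.vstack([
        pattern_weights(float(np.clip(s + rng.normal(0.0, 0.05), 0.0, 1.0)))
        for _ in REGIONS
    ])
    vw = rng.uniform(0.8, 1.2, len(REGIONS))
    return PatternProfile(regions=list(REGIONS), fractions=fractions,
                          volume_weights=vw / vw.sum())


def _ct_targets(s: float, group: str, rng: np.random.Generator) -> tuple[float, float, float, float]:
    lo, hi = LAA_RANGES[group]
    laa = float(np.clip(1.0 + 40.0 * s ** 1.6 + rng.uniform(-1.0, 1.0), lo, hi))
    plda = laa * rng.uniform(0.70, 0.95)
    laa856 = float(np.clip(2.2 * laa + 15.0 + rng.uniform(-4.0, 4.0), plda, 95.0))
    flda = float(np.clip(laa856 - plda + rng.uniform(-3.0, 3.0), 0.0, 100.0 - laa))
    return laa, laa856, plda, flda


def generate_cohort(spec: CohortSpec | None = None) -> list[CohortRecord]:
    """Generate the full synthetic cohort (seeded, reproducible)."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    records: list[CohortRecord] = []
    sizes = {"NE": spec.n_ne, "ME": spec.n_me, "SE": spec.n_se}
    means = dict(zip(GROUPS, spec.esi_group_means))
    sds = dict(zip(GROUPS, spec.esi_group_sds))
    idx = 0
    for group in GROUPS:
        for _ in range(sizes[group]):
            idx += 1
            target = float(np.clip(rng.normal(means[group], sds[group]), 0.0, 10.0))
            s = severity_from_esi(target)
            params = severity_to_params(s, rng)
            curve = generate_curve(params, noise_sd=spec.noise_sd,
                                   n_samples=spec.n_samples, rng=rng)
            laa, laa856, plda, flda = _ct_targets(s, group, rng)
            profile = generate_profile(s, rng)
            esi_fit = score_curve(curve).esi if spec.fit_curves else None
            rec = CohortRecord(
                subject_id=f"S{idx:04d}",
                group=group,
                severity=s,
                esi_true=params.true_esi,
                esi_fit=esi_fit,
                curve=curve,
                spiro=spirometric_indices(curve),
                laa950_insp=laa,
                laa856_exp=laa856,
                plda=plda,
                flda=flda,
                profile=profile,
            )
            assert emphysema_class(rec.laa950_insp) == group
            records.append(rec)
    return records


def cohort_table(records: list[CohortRecord]):
    """Cohort records as a tidy DataFrame (one row per subject)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "severity": [r.severity for r in records],
            "esi_true": [r.esi_true for r in records],
            "esi_fit": [r.esi_fit for r in records],
            "fev1": [r.spiro.fev1 for r in records],
            "fvc": [r.spiro.fvc for r in records],
            "fev1_fvc": [r.spiro.fev1_fvc_ratio for r in records],
            "laa950_insp": [r.laa950_insp for r in records],
            "laa856_exp": [r.laa856_exp for r in records],
            "plda": [r.plda for r in records],
            "flda": [r.flda for r in records],
            "cluster": [r.cluster for r in records],
        }
    )
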