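"""Synthetic 10-patient cohort with per-fraction DVHs for four schemes.

The real planning study (MRI-linac liver SBRT patients re-planned for
photon and proton delivery) cannot be redistributed, so this module
generates a virtual stand-in cohort with the same statistical structure:

* ten patients with fixed GTV and healthy-liver (liver-GTV) volumes,
  plus synthetic duodenum volumes and GTV-duodenum proximities drawn from
  a seeded generator (the real ones are unpublished);
* four schemes: non-adaptive/adaptive IMRT (5 mm / 2 mm margins) and
  non-adaptive/adaptive IMPT (3% range uncertainty plus 3 mm / 1 mm setup
  margins), proton doses weighted by a constant RBE of 1.1 at evaluation;
* plans of 50 Gy in 5 fractions normalized so the GTV mean is within 1% of
  prescription, obeying the planning constraints mean(liver-GTV) < 20 Gy
  and duodenum V35Gy(RBE) < 0.5 cc;
* daily anatomical perturbation that adaptation attenuates to a residual
  level, with coupled RNG streams so scheme contrasts are paired by
  construction.

The dose model is deliberately parametric, not image-based: each organ DVH
comes from an analytic cumulative-volume curve (uniform target peak;
exponential low-dose spill for the liver with a hot shell at prescription;
exponential spill plus a small hot tail near the penumbra dose for the
duodenum). Margins enlarge the spill/penumbra terms, protons halve the
integral spill and fall off more sharply, and adaptation shrinks both the
margin term and the day-to-day displacement response. All shape parameters
live in :class:`GeneratorConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Sequence

import numpy as np
from scipy.special import ndtr

from .core import DUODENUM, GTV, LIVER, DifferentialDVH, InvalidArgumentError
from .fractions import FractionDose, PLANNING_INDEX, SCHEMES, mean_dose, v_dose_cc


class GenerationError(RuntimeError):
    """Plan generation could not satisfy the planning constraints."""


# Fixed per-patient GTV and liver-GTV volumes (cc) of the study cohort.
TABLE1_VOLUMES: tuple[tuple[float, float], ...] = (
    (340.05, 1983.80),
    (20.67, 1434.67),
    (92.88, 1790.45),
    (28.94, 1165.49),
    (85.56, 1590.77),
    (100.92, 2659.70),
    (20.54, 1128.75),
    (59.77, 1061.49),
    (89.78, 964.46),
    (26.86, 1134.98),
)


@dataclass(frozen=True)
class PatientGeometry:
    patient_id: str
    gtv_volume: float
    liver_minus_gtv_volume: float
    duodenum_volume: float
    gtv_duodenum_proximity: float  # mm

    def __post_init__(self) -> None:
        for attr in ("gtv_volume", "liver_minus_gtv_volume", "duodenum_volume"):
            if getattr(self, attr) <= 0:
                raise InvalidArgumentError(f"{attr} must be positive")
        if self.gtv_duodenum_proximity < 0:
            raise InvalidArgumentError("proximity must be >= 0")


@dataclass(frozen=True)
class SchemeParams:
    """Delivery scheme: modality, adaptation flag and uncertainty terms."""

    name: str
    modality: str  # "photon" | "proton"
    adaptive: bool
    margin_mm: float
    range_uncertainty_pct: float
    interfraction_sigma_mm: float
    rbe_factor: float

    def __post_init__(self) -> None:
        if self.margin_mm <= 0:
            raise InvalidArgumentError("margin_mm must be positive")
        if self.modality not in ("photon", "proton"):
            raise InvalidArgumentError("modality must be photon or proton")


@dataclass
class GeneratorConfig:
    """Shape parameters of the synthetic dose model (defaults = study setup)."""

    prescription_gy: float = 50.0
    n_fractions: int = 5
    dvh_bin_gy: float = 0.1
    proton_rbe: float = 1.1

    # liver spill: cumulative volume above D is A * V * exp(-D / falloff),
    # capped at prescription (residual mass forms a hot shell at P)
    liver_base_mean_gy: float = 9.0          # photon mean liver dose at zero margin
    proton_integral_factor: float = 0.5      # proton integral spill vs photon
    margin_mean_coef_per_mm: float = 0.01    # relative mean-dose growth per mm margin
    liver_falloff_photon_gy: float = 14.0
    liver_falloff_proton_gy: float = 7.0

    # duodenum: low-dose spill plus a small hot tail at the penumbra dose
    duo_spill_fraction: float = 0.4
    duo_spill_falloff_gy: float = 3.0
    duo_floor_photon: float = 0.45           # hot dose floor as fraction of prescription
    duo_prox_weight_photon: float = 0.35     # proximity-dependent component
    duo_penumbra_photon_mm: float = 12.0
    duo_floor_proton: float = 0.20
    duo_prox_weight_proton: float = 0.35
    duo_penumbra_proton_mm: float = 6.0
    duo_margin_weight: float = 0.2           # mm of effective distance removed per mm margin
    duo_hot_cc: tuple = (0.2, 0.4)           # uniform range of hot-tail volume
    duo_hot_width_gy: float = 1.0

    # synthetic anatomy (real values unpublished)
    duo_volume_cc: tuple = (45.0, 90.0)
    duo_proximity_mm: tuple = (6.0, 10.0)

    # target dose spread and normalization jitter
    gtv_sigma_gy: float = 0.3
    gtv_jitter: float = 0.003

    # inter-patient / inter-plan lognormal variability (sigma of log)
    patient_sigma: float = 0.15
    plan_sigma: float = 0.07

    # day-to-day perturbation
    interfraction_sigma_mm: float = 3.0
    adaptive_attenuation: float = 0.25
    disp_liver_coef_per_mm: float = 0.01
    disp_duo_coef_per_mm: float = 0.01
    range_mm_per_pct: float = 0.5            # proton range error as extra mm per % uncertainty

    # planning constraints
    mean_liver_limit_gy: float = 20.0
    duo_v35_limit_cc: float = 0.5
    v35_threshold_gy: float = 35.0
    gtv_mean_tolerance: float = 0.01
    max_retries: int = 10


def default_schemes(config: GeneratorConfig | None = None) -> Dict[str, SchemeParams]:
    """The four study schemes, keyed by label."""
    cfg = config or GeneratorConfig()
    sig = cfg.interfraction_sigma_mm
    return {
        "imrt_nonadapt": SchemeParams("imrt_nonadapt", "photon", False, 5.0, 0.0, sig, 1.0),
        "imrt_adapt": SchemeParams("imrt_adapt", "photon", True, 2.0, 0.0, sig, 1.0),
        "impt_nonadapt": SchemeParams("impt_nonadapt", "proton", False, 3.0, 3.0, sig, cfg.proton_rbe),
        "impt_adapt": SchemeParams("impt_adapt", "proton", True, 1.0, 3.0, sig, cfg.proton_rbe),
    }


# --------------------------------------------------------------------------
# RNG stream layout: every draw is keyed by (seed, patient index, stream id)
# so paired contrasts share their coupled noise by construction.
# --------------------------------------------------------------------------

_STREAM_GEOMETRY = 0
_STREAM_PATIENT = 1
_STREAM_PLAN = 2
_STREAM_DAY = 3
_STREAM_RANGE = 4


def _rng(*key: int) -> np.random.Generator:
    # hash the stream key so that nearby keys give fully decorrelated streams
    digest = hashlib.sha256(":".join(str(k) for k in key).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:16], "little"))


def _patient_index(patient_id: str) -> int:
    digits = "".join(c for c in patient_id if c.isdigit())
    if not digits:
        raise InvalidArgumentError(f"patient_id {patient_id!r} carries no index")
    return int(digits)


def load_table1_fixture(seed: int = 0) -> list[PatientGeometry]:
    """Ten patients with the fixed GTV/liver volumes plus synthetic
    duodenum volume and GTV-duodenum proximity drawn from ``seed``."""
    cfg = GeneratorConfig()
    rng = _rng(seed, 0, _STREAM_GEOMETRY)
    out = []
    for i, (gtv, liver) in enumerate(TABLE1_VOLUMES, start=1):
        duo = float(rng.uniform(*cfg.duo_volume_cc))
        prox = float(rng.uniform(*cfg.duo_proximity_mm))
        out.append(PatientGeometry(f"p{i:02d}", gtv, liver, duo, prox))
    return out


# --------------------------------------------------------------------------
# Analytic DVH construction
# --------------------------------------------------------------------------


def _dvh_from_cumulative(name: str, total_cc: float, cum, max_dose: float,
                         bin_w: float) -> DifferentialDVH:
    """Bin an analytic cumulative-volume curve (cc at-or-above dose D).

    ``cum(0)`` is the irradiated volume; ``total_cc - cum(0)`` sits in an
    explicit zero-dose bin. ``cum`` must vanish at ``max_dose``.
    """
    edges = np.arange(0.0, max_dose + bin_w, bin_w)
    above = cum(edges)
    vols = above[:-1] - above[1:]
    centers = edges[:-1] + bin_w / 2.0
    cold = total_cc - float(above[0])
    doses = np.concatenate(([0.0], centers))
    volumes = np.concatenate(([max(cold, 0.0)], np.clip(vols, 0.0, None)))
    keep = volumes > 1e-9
    keep[0] = keep[0] or cold > 0
    if not np.any(keep):
        keep[0] = True
    doses, volumes = doses[keep], volumes[keep]
    return DifferentialDVH(name, doses, volumes, float(volumes.sum()))


@dataclass(frozen=True)
class _PlanShape:
    """Resolved per-plan dose-model parameters (after noise draws)."""

    gtv_center: float
    liver_spill_fraction: float
    liver_falloff: float
    duo_hot_dose: float
    duo_hot_cc: float
    duo_spill_fraction: float
    duo_spill_falloff: float


def _draw_plan_shape(geometry: PatientGeometry, scheme: SchemeParams,
                     cfg: GeneratorConfig, rng_plan: np.random.Generator,
                     patient_factor: float) -> _PlanShape:
    p = cfg.prescription_gy
    eps_liver = float(np.exp(rng_plan.normal(0.0, cfg.plan_sigma)))
    eps_duo = float(np.exp(rng_plan.normal(0.0, cfg.plan_sigma)))
    jitter = float(rng_plan.uniform(-cfg.gtv_jitter, cfg.gtv_jitter))
    hot_cc = float(rng_plan.uniform(*cfg.duo_hot_cc))

    proton = scheme.modality == "proton"
    modality_factor = cfg.proton_integral_factor if proton else 1.0
    falloff = cfg.liver_falloff_proton_gy if proton else cfg.liver_falloff_photon_gy
    mean_target = (cfg.liver_base_mean_gy * modality_factor
                   * (1.0 + cfg.margin_mean_coef_per_mm * scheme.margin_mm)
                   * patient_factor * eps_liver)
    # mean of the truncated-exponential spill is A * falloff * (1 - exp(-P/falloff))
    spill = mean_target / (falloff * (1.0 - np.exp(-p / falloff)))
    spill = min(spill, 0.9)

    floor = cfg.duo_floor_proton if proton else cfg.duo_floor_photon
    weight = cfg.duo_prox_weight_proton if proton else cfg.duo_prox_weight_photon
    penumbra = cfg.duo_penumbra_proton_mm if proton else cfg.duo_penumbra_photon_mm
    dist = max(0.0, geometry.gtv_duodenum_proximity
               - cfg.duo_margin_weight * scheme.margin_mm)
    # eps_duo scales the whole duodenal dose level: penumbra dose and spill alike
    hot_dose = p * (floor + weight * np.exp(-dist / penumbra)) * eps_duo
    hot_dose = float(min(hot_dose, 0.98 * p))

    return _PlanShape(p * (1.0 + jitter), spill, falloff, hot_dose, hot_cc,
                      cfg.duo_spill_fraction, cfg.duo_spill_falloff_gy * eps_duo)


def _build_plan_dvhs(geometry: PatientGeometry, shape: _PlanShape,
                     cfg: GeneratorConfig) -> Dict[str, DifferentialDVH]:
    p = cfg.prescription_gy
    bin_w = cfg.dvh_bin_gy
    max_dose = p + 2.0

    c, s = shape.gtv_center, cfg.gtv_sigma_gy

    def gtv_cum(d):
        return geometry.gtv_volume * ndtr((c - np.asarray(d, float)) / s)

    a, fall = shape.liver_spill_fraction, shape.liver_falloff
    vliv = geometry.liver_minus_gtv_volume

    def liver_cum(d):
        d = np.asarray(d, float)
        out = a * vliv * np.exp(-d / fall)
        return np.where(d <= p, out, 0.0)  # mass beyond P collapses into a hot shell at P

    vduo = geometry.duodenum_volume
    dh, w = shape.duo_hot_dose, cfg.duo_hot_width_gy

    def duo_cum(d):
        d = np.asarray(d, float)
        spill = shape.duo_spill_fraction * vduo * np.exp(-d / shape.duo_spill_falloff)
        hot = shape.duo_hot_cc * np.clip((dh - d) / w, 0.0, 1.0)
        return spill + hot

    return {
        GTV: _dvh_from_cumulative(GTV, geometry.gtv_volume, gtv_cum, max_dose, bin_w),
        LIVER: _dvh_from_cumulative(LIVER, vliv, liver_cum, max_dose, bin_w),
        DUODENUM: _dvh_from_cumulative(DUODENUM, vduo, duo_cum, max_dose, bin_w),
    }


def _check_constraints(dvhs: Dict[str, DifferentialDVH], scheme: SchemeParams,
                       cfg: GeneratorConfig) -> list[str]:
    problems = []
    ml = mean_dose(dvhs[LIVER])
    if ml >= cfg.mean_liver_limit_gy:
        problems.append(f"mean liver dose {ml:.2f} Gy >= {cfg.mean_liver_limit_gy} Gy")
    rbe = scheme.rbe_factor if scheme.modality == "proton" else 1.0
    duo = dvhs[DUODENUM].with_doses(dvhs[DUODENUM].bin_dose * rbe)
    v35 = v_dose_cc(duo, cfg.v35_threshold_gy)
    if v35 >= cfg.duo_v35_limit_cc:
        problems.append(f"duodenum V35Gy(RBE) {v35:.3f} cc >= {cfg.duo_v35_limit_cc} cc")
    mg = mean_dose(dvhs[GTV])
    if abs(mg - cfg.prescription_gy) > cfg.gtv_mean_tolerance * cfg.prescription_gy:
        problems.append(f"GTV mean {mg:.2f} Gy off prescription {cfg.prescription_gy} Gy")
    return problems


_SCHEME_CODE = {"photon": 0, "proton": 1}


def simulate_plan_dose(geometry: PatientGeometry, scheme: SchemeParams,
                       config: GeneratorConfig | None = None, seed: int = 0) -> FractionDose:
    """Generate one planning dose (fraction index 0, total course dose).

    Rejection-samples the plan-level noise until the planning constraints
    are met; raises :class:`GenerationError` with a diagnostic if the
    configuration is infeasible within ``max_retries`` attempts.
    """
    cfg = config or GeneratorConfig()
    pidx = _patient_index(geometry.patient_id)
    rng_pat = _rng(seed, pidx, _STREAM_PATIENT)
    patient_factor = float(np.exp(rng_pat.normal(0.0, cfg.patient_sigma)))
    rng_plan = _rng(seed, pidx, _STREAM_PLAN,
                    _SCHEME_CODE[scheme.modality], int(scheme.adaptive))
    problems: list[str] = []
    for _ in range(cfg.max_retries):
        shape = _draw_plan_shape(geometry, scheme, cfg, rng_plan, patient_factor)
        dvhs = _build_plan_dvhs(geometry, shape, cfg)
        problems = _check_constraints(dvhs, scheme, cfg)
        if not problems:
            return FractionDose(geometry.patient_id, scheme.name, PLANNING_INDEX, dvhs)
    raise GenerationError(
        f"could not satisfy planning constraints for {geometry.patient_id}/"
        f"{scheme.name} after {cfg.max_retries} attempts: {problems}"
    )


def perturb_fractions(plan: FractionDose, scheme: SchemeParams,
                      config: GeneratorConfig | None = None, seed: int = 0
                      ) -> list[FractionDose]:
    """Derive the N delivered fraction doses from a planning dose.

    Each day draws a signed anatomical displacement ~ N(0,
    interfraction_sigma); protons add a range-error term scaled by their
    range uncertainty. Displacement moves the OAR into or out of the dose
    spill, modelled as a multiplicative dose factor exp(coef * displacement)
    on the OAR DVHs; adaptation attenuates the displacement to the
    residual-margin level. Because the factor is convex in the
    displacement, the *expected* OAR dose of a non-adaptive course is
    always >= the adaptive one for the same draws, while individual days
    can go either way. Displacement streams are shared across schemes of
    one patient, so adaptive and non-adaptive courses see the same anatomy
    days. With zero displacement every fraction is exactly plan / N.
    """
    cfg = config or GeneratorConfig()
    n = cfg.n_fractions
    pidx = _patient_index(plan.patient_id)
    rng_day = _rng(seed, pidx, _STREAM_DAY)
    disp = rng_day.normal(0.0, scheme.interfraction_sigma_mm, size=n)
    if scheme.modality == "proton":
        rng_range = _rng(seed, pidx, _STREAM_RANGE)
        disp = disp + rng_range.normal(
            0.0, cfg.range_mm_per_pct * scheme.range_uncertainty_pct, size=n)
    att = cfg.adaptive_attenuation if scheme.adaptive else 1.0
    fractions = []
    for k in range(n):
        m_liver = float(np.exp(cfg.disp_liver_coef_per_mm * disp[k] * att))
        m_duo = float(np.exp(cfg.disp_duo_coef_per_mm * disp[k] * att))
        dvhs = {
            GTV: plan.dvhs[GTV].with_doses(plan.dvhs[GTV].bin_dose / n),
            LIVER: plan.dvhs[LIVER].with_doses(plan.dvhs[LIVER].bin_dose / n * m_liver),
            DUODENUM: plan.dvhs[DUODENUM].with_doses(plan.dvhs[DUODENUM].bin_dose / n * m_duo),
        }
        fractions.append(FractionDose(plan.patient_id, plan.scheme, k + 1, dvhs))
    return fractions


@dataclass
class CohortDataset:
    """Full synthetic dataset: planning + fraction records for all courses."""

    records: List[FractionDose]
    geometries: List[PatientGeometry]
    schemes: Dict[str, SchemeParams]
    config: GeneratorConfig
    seed: int

    def courses(self) -> Dict[tuple, List[FractionDose]]:
        out: Dict[tuple, List[FractionDose]] = {}
        for rec in self.records:
            out.setdefault((rec.patient_id, rec.scheme), []).append(rec)
        return out

    def manifest(self, dvh_file: str = "cohort_dvh.csv") -> list[dict]:
        return [
            {
                "patient_id": rec.patient_id,
                "scheme": rec.scheme,
                "fraction_index": rec.fraction_index,
                "file": dvh_file,
                "seed": self.seed,
            }
            for rec in self.records
        ]

    def manifest_hash(self) -> str:
        payload = json.dumps(self.manifest(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> CohortDataset:
    """Generate the default cohort: 10 patients x 4 schemes x (plan + N fractions)."""
    cfg = config or GeneratorConfig()
    geometries = load_table1_fixture(seed)
    schemes = default_schemes(cfg)
    records: List[FractionDose] = []
    for geom in geometries:
        for scheme in schemes.values():
            plan = simulate_plan_dose(geom, scheme, cfg, seed)
            records.append(plan)
            records.extend(perturb_fractions(plan, scheme, cfg, seed))
    return CohortDataset(records, geometries, schemes, cfg, seed)
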