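"""Lyman-Kutcher-Burman (LKB) dose-toxicity computation.

This module holds the radiobiological primitives used throughout the
package:

* :class:`DifferentialDVH` -- a binned dose-volume histogram for one
  structure (absolute volume per dose bin),
* linear-quadratic conversion of a physical course dose to the equivalent
  dose in each toxicity model's reference fractionation (EQD),
* reduction of a DVH to the generalized equivalent uniform dose
  ``EUD = (sum_i D_i^(1/n) V_i / V_tot)^n``,
* the LKB probit response ``NTCP = Phi((EUD - TD50) / (m * TD50))``,
* a registry of six published liver and duodenal toxicity models
  (Dawson RILD, Pursley ALBI and Child-Pugh, Pan gastric bleed,
  Holyoake grade >=3, Murphy grade 2-4).

Doses are in Gy, volumes in cc. Proton doses are physical unless noted;
a constant RBE weighting (conventionally 1.1) is applied by
:func:`ntcp_from_structure` before any LQ conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import ndtr


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class InvalidModelError(ValueError):
    """A model definition cannot be resolved (e.g. unknown reference scheme)."""


class InvalidPairingError(ValueError):
    """A DVH was paired with a model fitted for a different structure."""


class UnknownModelError(KeyError):
    """Requested model name is not in the registry."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class DifferentialDVH:
    """Differential dose-volume histogram for one structure.

    ``bin_dose`` holds strictly increasing bin-center doses in Gy (>= 0) and
    ``bin_volume`` the absolute volume in cc received at each dose.
    ``total_volume`` must equal the sum of the bin volumes (1e-6 relative).
    """

    structure_name: str
    bin_dose: np.ndarray
    bin_volume: np.ndarray
    total_volume: float

    def __post_init__(self) -> None:
        dose = np.asarray(self.bin_dose, dtype=np.float64)
        vol = np.asarray(self.bin_volume, dtype=np.float64)
        object.__setattr__(self, "bin_dose", dose)
        object.__setattr__(self, "bin_volume", vol)
        object.__setattr__(self, "total_volume", float(self.total_volume))
        if dose.ndim != 1 or vol.ndim != 1 or dose.shape != vol.shape:
            raise InvalidArgumentError("bin_dose and bin_volume must be 1-D and equal length")
        if dose.size == 0:
            raise InvalidArgumentError("DVH must contain at least one bin")
        if not (np.all(np.isfinite(dose)) and np.all(np.isfinite(vol))):
            raise InvalidArgumentError("DVH values must be finite")
        if np.any(dose < 0) or np.any(vol < 0):
            raise InvalidArgumentError("DVH doses and volumes must be non-negative")
        if dose.size > 1 and np.any(np.diff(dose) <= 0):
            raise InvalidArgumentError("bin_dose must be strictly increasing")
        s = float(vol.sum())
        if not math.isclose(s, self.total_volume, rel_tol=1e-6, abs_tol=1e-9):
            raise InvalidArgumentError(
                f"sum(bin_volume)={s!r} does not match total_volume={self.total_volume!r}"
            )

    def with_doses(self, new_dose: np.ndarray) -> "DifferentialDVH":
        """Return a copy with bin doses replaced (volumes untouched)."""
        return DifferentialDVH(self.structure_name, np.asarray(new_dose, dtype=np.float64),
                               self.bin_volume.copy(), self.total_volume)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DifferentialDVH):
            return NotImplemented
        return (
            self.structure_name == other.structure_name
            and self.total_volume == other.total_volume
            and np.array_equal(self.bin_dose, other.bin_dose)
            and np.array_equal(self.bin_volume, other.bin_volume)
        )

    __hash__ = None  # type: ignore[assignment]


PER_FRACTION_REF = "per_fraction_ref"
ISOEFFECT_25_FRACTIONS = "isoeffect_25_fractions"
SINGLE_FRACTION_25GY = "single_fraction_25Gy"

_KNOWN_SCHEMES = (PER_FRACTION_REF, ISOEFFECT_25_FRACTIONS, SINGLE_FRACTION_25GY)


@dataclass(frozen=True)
class RefScheme:
    """Reference fractionation a model's TD50 is expressed in.

    ``per_fraction_ref``: fixed dose per fraction ``dose_per_fraction``
    (e.g. the common EQD2 scale). ``single_fraction_25Gy``: equivalent dose
    of a single 25 Gy fraction. ``isoeffect_25_fractions``: total dose that
    is LQ-isoeffective when delivered in 25 fractions.
    """

    kind: str
    dose_per_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KNOWN_SCHEMES:
            raise InvalidModelError(f"unknown reference scheme kind {self.kind!r}")
        if self.kind == PER_FRACTION_REF:
            if self.dose_per_fraction is None or self.dose_per_fraction <= 0:
                raise InvalidModelError("per_fraction_ref requires a positive dose_per_fraction")


@dataclass(frozen=True)
class LKBModel:
    """One published LKB toxicity model.

    td50 is expressed on the model's reference-EQD scale; n is the volume
    effect (n -> 0 near-maximum dose, n -> large near-minimum dose);
    m is the probit slope; alpha_beta the LQ fractionation sensitivity.
    """

    name: str
    structure: str
    td50: float
    n: float
    m: float
    alpha_beta: float
    ref_scheme: RefScheme
    endpoint: str = ""

    def __post_init__(self) -> None:
        for attr in ("td50", "n", "m", "alpha_beta"):
            if getattr(self, attr) <= 0:
                raise InvalidModelError(f"{attr} must be positive")


@dataclass(frozen=True)
class NTCPValue:
    """NTCP evaluation result: the reduced EUD and the probit probability."""

    model_name: str
    eud: float
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise InvalidArgumentError("probability must lie in [0, 1]")
        if self.eud < 0:
            raise InvalidArgumentError("eud must be non-negative")


LIVER = "liver_minus_gtv"
DUODENUM = "duodenum"
GTV = "gtv"

_MODELS = (
    LKBModel("dawson_rild", LIVER, 43.3, 1.1, 0.18, 2.0,
             RefScheme(PER_FRACTION_REF, 1.5), "RILD grade >=3"),
    LKBModel("pursley_albi", LIVER, 32.0, 2.0, 1.5, 2.5,
             RefScheme(PER_FRACTION_REF, 2.0), "ALBI grade increase"),
    LKBModel("pursley_cp", LIVER, 19.0, 16.67, 0.8, 2.5,
             RefScheme(PER_FRACTION_REF, 2.0), "Child-Pugh increase > 2"),
    LKBModel("pan_gastric_bleed", DUODENUM, 180.0, 0.12, 0.49, 2.5,
             RefScheme(PER_FRACTION_REF, 2.0), "gastric bleed"),
    LKBModel("holyoake_g3", DUODENUM, 299.1, 0.193, 0.51, 4.0,
             RefScheme(ISOEFFECT_25_FRACTIONS), "GI toxicity grade >=3"),
    LKBModel("murphy_g2_4", DUODENUM, 24.6, 0.12, 0.23, 4.0,
             RefScheme(SINGLE_FRACTION_25GY), "duodenal toxicity grade 2-4"),
)


def model_registry() -> list[LKBModel]:
    """Return the six packaged LKB models (three liver, three duodenum)."""
    return list(_MODELS)


def get_model(name: str) -> LKBModel:
    for m in _MODELS:
        if m.name == name:
            return m
    raise UnknownModelError(name)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def _check_n_fractions(n_fractions: int) -> int:
    if int(n_fractions) != n_fractions or n_fractions < 1:
        raise InvalidArgumentError("n_fractions must be a positive integer")
    return int(n_fractions)


def _eqd_fixed_ref(dose: np.ndarray, n_fractions: int, alpha_beta: float,
                   d_ref: float) -> np.ndarray:
    fx = dose / n_fractions
    return dose * (fx + alpha_beta) / (d_ref + alpha_beta)


def _eqd_isoeffect(dose: np.ndarray, n_fractions: int, alpha_beta: float,
                   ref_fractions: int = 25) -> np.ndarray:
    # positive root of X * (X/ref_fractions + ab) = D * (D/n_fractions + ab)
    rhs = dose * (dose / n_fractions + alpha_beta)
    ab = alpha_beta
    return (ref_fractions / 2.0) * (-ab + np.sqrt(ab * ab + (4.0 / ref_fractions) * rhs))


def convert_to_eqd(dvh: DifferentialDVH, n_fractions: int, model: LKBModel) -> DifferentialDVH:
    """Convert total physical bin doses to the model's reference-scheme EQD.

    The per-bin fraction dose is the bin dose divided by ``n_fractions``
    (equal-fraction assumption). Volumes are unchanged; zero dose maps to
    zero for every scheme.
    """
    n_fractions = _check_n_fractions(n_fractions)
    scheme = model.ref_scheme
    if scheme.kind == PER_FRACTION_REF:
        eqd = _eqd_fixed_ref(dvh.bin_dose, n_fractions, model.alpha_beta,
                             scheme.dose_per_fraction)
    elif scheme.kind == SINGLE_FRACTION_25GY:
        eqd = _eqd_fixed_ref(dvh.bin_dose, n_fractions, model.alpha_beta, 25.0)
    elif scheme.kind == ISOEFFECT_25_FRACTIONS:
        eqd = _eqd_isoeffect(dvh.bin_dose, n_fractions, model.alpha_beta)
    else:  # pragma: no cover - RefScheme rejects unknown kinds at construction
        raise InvalidModelError(f"unknown reference scheme {scheme.kind!r}")
    return dvh.with_doses(eqd)


def physical_dose_for_eqd(eqd: float, n_fractions: int, model: LKBModel) -> float:
    """Invert :func:`convert_to_eqd` for a uniform dose.

    Returns the total physical course dose (in ``n_fractions`` equal
    fractions) whose reference-scheme equivalent is ``eqd``.
    """
    n_fractions = _check_n_fractions(n_fractions)
    if eqd < 0:
        raise InvalidArgumentError("eqd must be non-negative")
    ab = model.alpha_beta
    scheme = model.ref_scheme
    if scheme.kind == PER_FRACTION_REF:
        rhs = eqd * (scheme.dose_per_fraction + ab)
    elif scheme.kind == SINGLE_FRACTION_25GY:
        rhs = eqd * (25.0 + ab)
    else:
        rhs = eqd * (eqd / 25.0 + ab)
    # positive root of D * (D/n_fractions + ab) = rhs
    return (n_fractions / 2.0) * (-ab + math.sqrt(ab * ab + 4.0 * rhs / n_fractions))


def eud(dvh: DifferentialDVH, n: float) -> float:
    """Generalized equivalent uniform dose ``(sum_i D_i^(1/n) V_i/V_tot)^n``.

    Computed with max-dose factoring so large exponents 1/n (small n,
    near-maximum models) cannot overflow: all dose ratios are <= 1.
    """
    if n <= 0:
        raise InvalidArgumentError("volume-effect parameter n must be positive")
    if dvh.total_volume <= 0 or float(dvh.bin_volume.sum()) <= 0:
        raise InvalidArgumentError("DVH has no volume")
    a = 1.0 / n
    w = dvh.bin_volume / dvh.total_volume
    mask = (dvh.bin_dose > 0) & (w > 0)
    if not np.any(mask):
        return 0.0
    d = dvh.bin_dose[mask]
    wm = w[mask]
    m = float(d.max())
    # sum of w * (D/M)^a in log space via the ratios themselves (<= 1)
    s = float(np.sum(wm * np.exp(a * np.log(d / m))))
    return m * s ** n


def lkb_ntcp(eud_gy: float, model: LKBModel) -> NTCPValue:
    """LKB probit response: ``Phi((EUD - TD50) / (m * TD50))``.

    At zero dose the prediction is ``Phi(-1/m) > 0``, i.e. the models carry
    a disease-related baseline risk independent of the treatment.
    """
    if eud_gy < 0:
        raise InvalidArgumentError("eud must be non-negative")
    t = (eud_gy - model.td50) / (model.m * model.td50)
    return NTCPValue(model.name, float(eud_gy), float(ndtr(t)))


def ntcp_from_structure(dvh: DifferentialDVH, model: LKBModel, n_fractions: int,
                        rbe_factor: float = 1.0) -> NTCPValue:
    """Full dose-to-probability chain for one structure DVH.

    Applies the constant RBE weighting (1.0 for photons, conventionally 1.1
    for proton physical dose), converts to the model's reference EQD,
    reduces to EUD with the model's volume effect, and evaluates the probit.
    """
    if dvh.structure_name != model.structure:
        raise InvalidPairingError(
            f"DVH structure {dvh.structure_name!r} does not match model structure "
            f"{model.structure!r}"
        )
    if rbe_factor <= 0:
        raise InvalidArgumentError("rbe_factor must be positive")
    weighted = dvh.with_doses(dvh.bin_dose * rbe_factor)
    eqd_dvh = convert_to_eqd(weighted, n_fractions, model)
    e = eud(eqd_dvh, model.n)
    return lkb_ntcp(e, model)
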