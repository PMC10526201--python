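"""Fraction-NTCP / treatment-NTCP procedure and plan dose metrics.

Accumulating daily doses deformably is unreliable when structures are
re-drawn every day, so each delivered fraction dose is instead scaled to
the full prescription (multiplied by the number of fractions) and scored
with the NTCP models on its own. A five-fraction course therefore yields
five "fraction NTCPs"; their mean is the treatment-NTCP point estimate and
their min/max the reported range. The planning dose is scored the same way
(stored as fraction index 0) so both share one code path.

Also provides the dosimetric plan metrics used for scheme comparison:
volume-weighted mean dose, VxGy in absolute cc, and the near-maximum dose
D(tail_volume cc) with a 0.5 cc default tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DUODENUM,
    GTV,
    LIVER,
    DifferentialDVH,
    InvalidArgumentError,
    InvalidPairingError,
    LKBModel,
    NTCPValue,
    model_registry,
    ntcp_from_structure,
)

REQUIRED_STRUCTURES = (GTV, LIVER, DUODENUM)

SCHEMES = ("imrt_nonadapt", "imrt_adapt", "impt_nonadapt", "impt_adapt")

PLANNING_INDEX = 0


@dataclass(frozen=True)
class FractionDose:
    """Per-structure DVHs for one fraction of one patient under one scheme.

    ``fraction_index`` 0 denotes the planning dose; delivered fractions are
    numbered 1..N and hold single-fraction doses.
    """

    patient_id: str
    scheme: str
    fraction_index: int
    dvhs: Mapping[str, DifferentialDVH]

    def __post_init__(self) -> None:
        if self.fraction_index < 0:
            raise InvalidArgumentError("fraction_index must be >= 0")
        missing = [s for s in REQUIRED_STRUCTURES if s not in self.dvhs]
        if missing:
            raise InvalidArgumentError(
                f"fraction for {self.patient_id!r}/{self.scheme!r} is missing "
                f"required structures: {missing}"
            )


@dataclass(frozen=True)
class NTCPResult:
    """Planning, fraction, and treatment NTCP summary for one course/model."""

    patient_id: str
    scheme: str
    model_name: str
    planning_ntcp: float
    fraction_ntcps: tuple
    treatment_ntcp: float
    ntcp_range: tuple

    def __post_init__(self) -> None:
        fr = tuple(float(v) for v in self.fraction_ntcps)
        object.__setattr__(self, "fraction_ntcps", fr)
        object.__setattr__(self, "ntcp_range",
                           (float(self.ntcp_range[0]), float(self.ntcp_range[1])))
        if not fr:
            raise InvalidArgumentError("fraction_ntcps must be non-empty")
        lo, hi = self.ntcp_range
        if not (np.isclose(lo, min(fr)) and np.isclose(hi, max(fr))):
            raise InvalidArgumentError("ntcp_range must equal (min, max) of fraction_ntcps")
        if not (lo - 1e-12 <= self.treatment_ntcp <= hi + 1e-12):
            raise InvalidArgumentError("treatment_ntcp must lie within ntcp_range")


# --------------------------------------------------------------------------
# Fraction NTCP procedure
# --------------------------------------------------------------------------


def scale_fraction_to_prescription(fraction: FractionDose, n_fractions: int) -> FractionDose:
    """Multiply every bin dose by ``n_fractions``; volumes untouched."""
    if n_fractions < 1:
        raise InvalidArgumentError("n_fractions must be >= 1")
    scaled = {name: dvh.with_doses(dvh.bin_dose * n_fractions)
              for name, dvh in fraction.dvhs.items()}
    return FractionDose(fraction.patient_id, fraction.scheme, fraction.fraction_index, scaled)


def fraction_ntcps(fractions: Sequence[FractionDose], model: LKBModel,
                   rbe_factor: float = 1.0) -> list[float]:
    """NTCP of each fraction dose scaled to the prescription.

    All fractions must come from a single (patient, scheme) course; the
    scaled course is treated as N fractions of the observed fraction dose
    when re-converting to EQD.
    """
    if not fractions:
        raise InvalidArgumentError("need at least one fraction")
    ids = {(f.patient_id, f.scheme) for f in fractions}
    if len(ids) != 1:
        raise InvalidArgumentError(f"fractions mix courses: {sorted(ids)}")
    indices = [f.fraction_index for f in fractions]
    if len(set(indices)) != len(indices):
        raise InvalidArgumentError("fraction_index values must be unique within a course")
    n = len(fractions)
    out = []
    for frac in sorted(fractions, key=lambda f: f.fraction_index):
        if model.structure not in frac.dvhs:
            raise InvalidPairingError(
                f"fraction lacks structure {model.structure!r} required by {model.name}"
            )
        scaled = scale_fraction_to_prescription(frac, n)
        value = ntcp_from_structure(scaled.dvhs[model.structure], model, n, rbe_factor)
        out.append(value.probability)
    return out


def treatment_ntcp(fraction_probs: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Treatment-NTCP summary: arithmetic mean and (min, max) range."""
    if len(fraction_probs) == 0:
        raise InvalidArgumentError("fraction NTCP list must be non-empty")
    arr = np.asarray(fraction_probs, dtype=float)
    return float(arr.mean()), (float(arr.min()), float(arr.max()))


def evaluate_course(records: Sequence[FractionDose], model: LKBModel,
                    rbe_factor: float = 1.0) -> NTCPResult:
    """Score one (patient, scheme) course with one model.

    ``records`` must contain the planning dose (fraction index 0, total
    course dose) and the delivered fractions (indices 1..N, single-fraction
    doses).
    """
    plan = [r for r in records if r.fraction_index == PLANNING_INDEX]
    fracs = [r for r in records if r.fraction_index != PLANNING_INDEX]
    if len(plan) != 1:
        raise InvalidArgumentError("course needs exactly one planning record (index 0)")
    if not fracs:
        raise InvalidArgumentError("course has no delivered fractions")
    n = len(fracs)
    planning = ntcp_from_structure(plan[0].dvhs[model.structure], model, n, rbe_factor)
    probs = fraction_ntcps(fracs, model, rbe_factor)
    mean, rng = treatment_ntcp(probs)
    return NTCPResult(plan[0].patient_id, plan[0].scheme, model.name,
                      planning.probability, tuple(probs), mean, rng)


def evaluate_courses(records: Iterable[FractionDose],
                     models: Sequence[LKBModel] | None = None,
                     proton_rbe: float = 1.1) -> list[NTCPResult]:
    """Score every (patient, scheme) course in ``records`` with every model.

    Schemes whose label starts with ``impt`` are treated as proton courses
    and weighted by ``proton_rbe``; all others use RBE 1.0.
    """
    if models is None:
        models = model_registry()
    courses: Dict[tuple, list[FractionDose]] = {}
    for rec in records:
        courses.setdefault((rec.patient_id, rec.scheme), []).append(rec)
    results = []
    for (pid, scheme), recs in sorted(courses.items()):
        rbe = proton_rbe if scheme.startswith("impt") else 1.0
        for model in models:
            results.append(evaluate_course(recs, model, rbe))
    return results


def results_table(results: Sequence[NTCPResult]) -> pd.DataFrame:
    """Long-format results table, one row per (course, model, fraction)."""
    rows = []
    for r in results:
        for k, p in enumerate(r.fraction_ntcps, start=1):
            rows.append({
                "patient_id": r.patient_id,
                "scheme": r.scheme,
                "model": r.model_name,
                "planning_ntcp": r.planning_ntcp,
                "fraction_index": k,
                "fraction_ntcp": p,
                "treatment_ntcp": r.treatment_ntcp,
                "ntcp_min": r.ntcp_range[0],
                "ntcp_max": r.ntcp_range[1],
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Dosimetric plan metrics
# --------------------------------------------------------------------------


def mean_dose(dvh: DifferentialDVH) -> float:
    """Volume-weighted mean dose ``sum_i D_i V_i / V_tot`` in Gy."""
    if dvh.total_volume <= 0:
        raise InvalidArgumentError("DVH has no volume")
    return float(np.sum(dvh.bin_dose * dvh.bin_volume) / dvh.total_volume)


def v_dose_cc(dvh: DifferentialDVH, threshold: float) -> float:
    """Absolute volume (cc) receiving at least ``threshold`` Gy."""
    if threshold < 0:
        raise InvalidArgumentError("threshold must be >= 0")
    return float(dvh.bin_volume[dvh.bin_dose >= threshold].sum())


def near_max_dose(dvh: DifferentialDVH, tail_volume: float = 0.5) -> float:
    """Near-maximum dose: smallest d with ``v_dose_cc(d) <= tail_volume``.

    This is the D0.5cc convention by default. If ``tail_volume`` exceeds the
    total volume the minimum bin dose is returned (degenerate case); if even
    the hottest bin holds more than ``tail_volume`` the maximum bin dose is
    returned.
    """
    if tail_volume <= 0:
        raise InvalidArgumentError("tail_volume must be positive")
    # cumulative volume at-or-above each bin dose
    suffix = np.cumsum(dvh.bin_volume[::-1])[::-1]
    idx = np.nonzero(suffix <= tail_volume)[0]
    if idx.size == 0:
        return float(dvh.bin_dose[-1])
    return float(dvh.bin_dose[idx[0]])
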