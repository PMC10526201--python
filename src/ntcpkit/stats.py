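"""Paired significance testing between delivery schemes, per NTCP model.

Scheme contrasts are evaluated on the per-patient treatment NTCPs with
two-sided paired t-tests at alpha = 0.05, without multiplicity correction
(a deliberate caveat, documented in the methods note). Degenerate cases
follow fixed conventions: all-zero differences give t = 0, p = 1; a
constant non-zero difference gives an infinite t and p = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from .core import InvalidArgumentError
from .fractions import NTCPResult, SCHEMES


class MissingDataError(ValueError):
    """The results grid is incomplete; lists the absent cells."""


#: Scheme contrasts of interest, label -> (x scheme, y scheme).
COMPARISONS: Dict[str, tuple[str, str]] = {
    "imrt_vs_impt_nonadapt": ("imrt_nonadapt", "impt_nonadapt"),
    "imrt_vs_impt_adapt": ("imrt_adapt", "impt_adapt"),
    "adapt_vs_nonadapt_imrt": ("imrt_adapt", "imrt_nonadapt"),
    "adapt_vs_nonadapt_impt": ("impt_adapt", "impt_nonadapt"),
}


@dataclass(frozen=True)
class CohortComparison:
    model_name: str
    comparison: str
    x: tuple
    y: tuple
    t_statistic: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise InvalidArgumentError("paired arrays must have equal length")
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidArgumentError("p_value must lie in [0, 1]")


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on the differences x - y.

    Returns ``(t_statistic, p_value)`` with n-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise InvalidArgumentError("need at least two pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t_stat = mean / (sd / math.sqrt(n))
    p = 2.0 * float(student_t.sf(abs(t_stat), n - 1))
    return t_stat, p


def _treatment_grid(results: Iterable[NTCPResult]) -> pd.DataFrame:
    rows = [
        {"patient_id": r.patient_id, "scheme": r.scheme, "model": r.model_name,
         "treatment_ntcp": r.treatment_ntcp}
        for r in results
    ]
    if not rows:
        raise MissingDataError("no results provided")
    return pd.DataFrame(rows)


def build_comparison_table(results: Iterable[NTCPResult], alpha: float = 0.05
                           ) -> list[CohortComparison]:
    """All scheme contrasts for every model present in ``results``.

    Requires the full (patient x scheme) grid for each model; an
    incomplete grid raises :class:`MissingDataError` naming the absent
    cells. No multiple-testing correction is applied.
    """
    grid = _treatment_grid(results)
    patients = sorted(grid["patient_id"].unique())
    models = sorted(grid["model"].unique())
    have = set(zip(grid["patient_id"], grid["scheme"], grid["model"]))
    missing = [
        (p, s, m)
        for m in models for s in SCHEMES for p in patients
        if (p, s, m) not in have
    ]
    if missing:
        raise MissingDataError(f"missing result cells: {missing}")
    pivot = grid.set_index(["model", "scheme", "patient_id"])["treatment_ntcp"]
    out = []
    for model in models:
        for label, (sx, sy) in COMPARISONS.items():
            x = tuple(pivot.loc[(model, sx, p)] for p in patients)
            y = tuple(pivot.loc[(model, sy, p)] for p in patients)
            t_stat, p_val = paired_t_test(x, y)
            out.append(CohortComparison(model, label, x, y, t_stat, p_val,
                                        p_val < alpha))
    return out


def comparison_frame(comparisons: Sequence[CohortComparison]) -> pd.DataFrame:
    """Pivot of p-values, one row per model and one column per contrast."""
    df = pd.DataFrame(
        {"model": c.model_name, "comparison": c.comparison, "p_value": c.p_value}
        for c in comparisons
    )
    return df.pivot(index="model", columns="comparison", values="p_value")[
        list(COMPARISONS)
    ]


def comparison_report(comparisons: Sequence[CohortComparison], alpha: float = 0.05) -> str:
    """Plain-text report flagging significant contrasts with an asterisk."""
    lines = [f"Paired t-tests on treatment NTCPs (alpha = {alpha}, two-sided)", ""]
    frame = comparison_frame(comparisons)
    header = f"{'model':<20}" + "".join(f"{c:>26}" for c in frame.columns)
    lines.append(header)
    for model, row in frame.iterrows():
        cells = "".join(
            f"{row[c]:>25.4f}{'*' if row[c] < alpha else ' '}" for c in frame.columns
        )
        lines.append(f"{model:<20}{cells}")
    lines.append("")
    lines.append("* p < alpha")
    return "\n".join(lines)
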