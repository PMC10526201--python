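"""DVH exchange format and run configuration.

DVH records travel as a flat UTF-8 CSV with one row per dose bin and the
header ``patient_id,scheme,fraction_index,structure,bin_dose_gy,
bin_volume_cc``. Fraction index 0 denotes the planning (total course)
dose; indices 1..N are single-fraction doses. The writer emits full float
repr so a read of a written file reproduces the dataset bit-exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import GeneratorConfig
from .core import DifferentialDVH, InvalidArgumentError
from .fractions import FractionDose

DVH_COLUMNS = ["patient_id", "scheme", "fraction_index", "structure",
               "bin_dose_gy", "bin_volume_cc"]


class DVHParseError(ValueError):
    """A DVH file violates the schema; message carries the line number."""


def write_dvh_file(records: Iterable[FractionDose], path) -> None:
    """Write fraction records as the flat bin-per-row CSV dialect."""
    frames = []
    for rec in records:
        for name in sorted(rec.dvhs):
            dvh = rec.dvhs[name]
            frames.append(pd.DataFrame({
                "patient_id": rec.patient_id,
                "scheme": rec.scheme,
                "fraction_index": rec.fraction_index,
                "structure": name,
                "bin_dose_gy": dvh.bin_dose,
                "bin_volume_cc": dvh.bin_volume,
            }))
    if not frames:
        raise InvalidArgumentError("no records to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dvh_file(path) -> List[FractionDose]:
    """Read a DVH CSV back into fraction records (inverse of the writer)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "scheme": str, "structure": str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DVHParseError(f"{path}: empty file, no DVH records") from None
    unknown = [c for c in df.columns if c not in DVH_COLUMNS]
    if unknown:
        raise DVHParseError(f"{path}: unknown columns {unknown}")
    absent = [c for c in DVH_COLUMNS if c not in df.columns]
    if absent:
        raise DVHParseError(f"{path}: missing columns {absent}")
    if len(df) == 0:
        raise DVHParseError(f"{path}: no DVH records")
    for col in ("bin_dose_gy", "bin_volume_cc"):
        bad = df.index[~np.isfinite(df[col]) | (df[col] < 0)]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise DVHParseError(f"{path}: invalid {col} at line {int(bad[0]) + 2}")
    records = []
    keys = ["patient_id", "scheme", "fraction_index"]
    for (pid, scheme, idx), frac_df in df.groupby(keys, sort=False):
        dvhs: Dict[str, DifferentialDVH] = {}
        for structure, sdf in frac_df.groupby("structure", sort=False):
            dose = sdf["bin_dose_gy"].to_numpy()
            vol = sdf["bin_volume_cc"].to_numpy()
            try:
                dvhs[structure] = DifferentialDVH(structure, dose, vol, float(vol.sum()))
            except InvalidArgumentError as exc:
                line = int(sdf.index[0]) + 2
                raise DVHParseError(f"{path}: malformed DVH near line {line}: {exc}") from exc
        records.append(FractionDose(str(pid), str(scheme), int(idx), dvhs))
    return records


@dataclass
class RunConfig:
    """Everything that determines a pipeline run (plus the seed)."""

    alpha: float = 0.05
    seed: int = 0
    models: List[str] = field(default_factory=list)  # empty = all registered
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    # convenience views of the prescription-level settings
    @property
    def prescription_gy(self) -> float:
        return self.generator.prescription_gy

    @property
    def n_fractions(self) -> int:
        return self.generator.n_fractions

    @property
    def rbe_factor(self) -> float:
        return self.generator.proton_rbe

    @property
    def dvh_bin_gy(self) -> float:
        return self.generator.dvh_bin_gy

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "seed": self.seed, "models": list(self.models),
                "generator": asdict(self.generator)}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        gen = data.pop("generator", {}) or {}
        known = {f.name for f in fields(GeneratorConfig)}
        unknown = set(gen) - known
        if unknown:
            raise InvalidArgumentError(f"unknown generator settings: {sorted(unknown)}")
        gen_cfg = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in gen.items()})
        allowed = {"alpha", "seed", "models"}
        bad = set(data) - allowed
        if bad:
            raise InvalidArgumentError(f"unknown config settings: {sorted(bad)}")
        return cls(alpha=data.get("alpha", 0.05), seed=data.get("seed", 0),
                   models=list(data.get("models", [])), generator=gen_cfg)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
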