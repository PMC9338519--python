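"""Tab-separated input/output and YAML configuration handling."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core import SummaryTable, VValueResult  # noqa: F401
from .simulate import SimulationConfig

__all__ = [
    "read_sumstats",
    "read_table",
    "write_results",
    "load_sim_config",
]

# %.17g round-trips IEEE doubles exactly through text.
_FLOAT_FMT = "%.17g"


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_sumstats(
    path,
    q_col: str = "q",
    group_col: str = "group",
    allow_p_clamp: bool = False,
) -> SummaryTable:
    """Read and validate a per-SNP summary-statistics table.

    Requires tab-separated text with a header and columns ``snp``, ``p``,
    ``q`` (or *q_col*) and ``group`` (or *group_col*); optional ``chrom`` and
    1-based ``pos``.  Validation failures name the offending rows and column.
    """
    return SummaryTable.from_dataframe(
        read_table(path), q_col=q_col, group_col=group_col, allow_p_clamp=allow_p_clamp
    )


def write_results(
    table: SummaryTable, results: Sequence[VValueResult], path
) -> None:
    """Write input columns plus per-iteration ``v_iterK`` / ``fdr_iterK`` columns.

    Floats are printed with 17 significant digits so that reading the file
    back reproduces the values bit-for-bit.
    """
    df = table.to_dataframe()
    for res in results:
        df[f"v_iter{res.iteration}"] = res.v
        df[f"fdr_iter{res.iteration}"] = res.fdr
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_sim_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML mapping; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a YAML mapping of config fields")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    return SimulationConfig(**raw)
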