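"""CSV curve tables and run configuration.

Concentration-response data travel as long-format CSV with the columns
``agonist_id, pathway_id, replicate, concentration_M, response`` (optional
``basal`` and ``e_max_system``).  Concentrations are molar; scientific
notation is accepted.  Reading validates the table and reports offending
rows by line number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .simulate import ResponseCurve

__all__ = [
    "REQUIRED_COLUMNS",
    "CurveTableError",
    "read_curves",
    "write_curves",
    "RunConfig",
]

REQUIRED_COLUMNS = (
    "agonist_id",
    "pathway_id",
    "replicate",
    "concentration_M",
    "response",
)


class CurveTableError(ValueError):
    """Malformed curve table; the message lists offending CSV line numbers."""


def read_curves(path) -> list[ResponseCurve]:
    """Read a long-format CSV into curves grouped by (agonist, pathway, replicate).

    Points are sorted by concentration within each group.  Raises
    :class:`CurveTableError` on missing columns, non-positive or unparsable
    concentrations, duplicate keys or an empty file, naming the CSV line
    numbers involved (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise CurveTableError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CurveTableError(f"{path}: missing columns {missing}")
    # CSV line number: header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2

    def _at(mask) -> list[int]:
        return [int(v) for v in lines[mask.to_numpy()]]

    conc = pd.to_numeric(df["concentration_M"], errors="coerce")
    bad = conc.isna() | (conc <= 0)
    if bad.any():
        raise CurveTableError(
            f"{path}: non-positive or unparsable concentration_M at lines {_at(bad)}"
        )
    resp = pd.to_numeric(df["response"], errors="coerce")
    if resp.isna().any():
        raise CurveTableError(
            f"{path}: unparsable response at lines {_at(resp.isna())}"
        )
    df = df.assign(concentration_M=conc, response=resp)

    keys = ["agonist_id", "pathway_id", "replicate", "concentration_M"]
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        raise CurveTableError(
            f"{path}: duplicate (agonist, pathway, replicate, concentration) keys "
            f"at lines {_at(dup)}"
        )

    curves = []
    for (agonist, pathway, rep), grp in df.groupby(
        ["agonist_id", "pathway_id", "replicate"], sort=True
    ):
        grp = grp.sort_values("concentration_M")
        meta = {"agonist": agonist, "pathway": pathway}
        for opt in ("basal", "e_max_system"):
            if opt in grp.columns and grp[opt].notna().any():
                meta[opt] = float(grp[opt].iloc[0])
        curves.append(
            ResponseCurve(
                grp["concentration_M"].to_numpy(),
                grp["response"].to_numpy(),
                replicate_id=int(rep),
                meta=meta,
            )
        )
    return curves


def write_curves(curves: Iterable[ResponseCurve], path) -> None:
    """Write curves to the long-format CSV schema (17 significant digits)."""
    rows = []
    for c in curves:
        for conc, resp in zip(c.concentrations, c.responses):
            rows.append(
                {
                    "agonist_id": c.meta.get("agonist", "A"),
                    "pathway_id": c.meta.get("pathway", "P"),
                    "replicate": c.replicate_id if c.replicate_id is not None else 1,
                    "concentration_M": conc,
                    "response": resp,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Validated run configuration, serialized alongside outputs.

    Grid bounds are log10 molar; ``e_max_system`` is the normalization
    target (the fitting cap); ``noise_sd``/``replicates`` apply to
    simulation commands only.
    """

    grid_log10_min: float = -10.0
    grid_log10_max: float = -2.0
    grid_points: int = 61
    e_max_system: float = 1.0
    e_max_cap: float = 1.0
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        if not self.grid_log10_min < self.grid_log10_max:
            raise ValueError("grid_log10_min must be below grid_log10_max")
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.e_max_system > 0 or not self.e_max_cap > 0:
            raise ValueError("e_max values must be > 0")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        return cls(**data)

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
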