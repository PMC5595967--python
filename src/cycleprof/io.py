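"""Readers and writers for the pipeline's delimited tables.

Phase tables travel as CSV with columns compound,g1,s,g2m,subg1 (percent,
serialized at 2 decimals); the same reader ingests a supplementary-style
XLSX spreadsheet through a user-supplied column-name mapping.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from cycleprof.cci import Fingerprint
from cycleprof.errors import ValidationError

STANDARD_COLUMNS = ("compound", "g1", "s", "g2m", "subg1")


def _load_frame(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_profile_table(
    path, column_map: dict[str, str] | None = None
) -> tuple[list[Fingerprint], list[str]]:
    """Load a per-compound phase-percentage table.

    ``column_map`` maps standard names (compound, g1, s, g2m, subg1) to the
    file's column headers when they differ.  Returns the fingerprints plus
    the names of rows whose phases do not sum to 100 +/- 0.5 — those rows
    are loaded and flagged, never dropped.
    """
    path = Path(path)
    df = _load_frame(path)
    column_map = column_map or {}
    resolved = {std: column_map.get(std, std) for std in STANDARD_COLUMNS}
    missing = [col for col in resolved.values() if col not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    fingerprints, flagged = [], []
    for _, row in df.iterrows():
        fp = Fingerprint(
            compound=str(row[resolved["compound"]]),
            g1=float(row[resolved["g1"]]),
            s=float(row[resolved["s"]]),
            g2m=float(row[resolved["g2m"]]),
            subg1=float(row[resolved["subg1"]]),
        )
        fingerprints.append(fp)
        if not fp.normalized:
            flagged.append(fp.compound)
    return fingerprints, flagged


def write_phase_table(fingerprints: list[Fingerprint], path, well_ids=None) -> None:
    """Percentages at 2 decimals; optional leading well_id column."""
    rows = []
    for i, fp in enumerate(fingerprints):
        rec = {}
        if well_ids is not None:
            rec["well_id"] = well_ids[i]
        rec.update({"compound": fp.compound, "g1": round(fp.g1, 2), "s": round(fp.s, 2),
                    "g2m": round(fp.g2m, 2), "subg1": round(fp.subg1, 2)})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.2f")


def read_viability_table(path) -> pd.DataFrame:
    """Long-format luminescence plate: well_id, role, compound, reading."""
    df = pd.read_csv(path, dtype={"well_id": str, "role": str, "compound": str})
    needed = {"well_id", "role", "compound", "reading"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"viability table missing columns {sorted(needed - set(df.columns))}")
    return df


def read_dose_table(path) -> pd.DataFrame:
    """Long-format dose series: compound, dose_uM, replicate, reading|response."""
    df = pd.read_csv(path, dtype={"compound": str})
    if "response" not in df.columns and "reading" in df.columns:
        df = df.rename(columns={"reading": "response"})
    needed = {"compound", "dose_uM", "response"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"dose table missing columns {sorted(needed - set(df.columns))}")
    return df
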