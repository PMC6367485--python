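"""CSV schemas and validation for the pipeline's on-disk interfaces.

Every stage exchanges data through these declared schemas only.  A schema is
a list of column rules (name, dtype kind, positivity); :func:`validate_csv`
reports every violation with its row index rather than failing fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ColumnRule", "SCHEMAS", "validate_csv", "validate_dataframe"]


@dataclass(frozen=True)
class ColumnRule:
    name: str
    kind: str = "numeric"      # "numeric" | "text"
    positive: bool = False
    nonnegative: bool = False
    increasing: bool = False


SCHEMAS: dict[str, list[ColumnRule]] = {
    "populations": [
        ColumnRule("label", kind="text"),
        ColumnRule("diameter_nm", positive=True),
    ],
    "series_manifest": [
        ColumnRule("label", kind="text"),
        ColumnRule("nominal_nm", positive=True),
        ColumnRule("n", positive=True),
        ColumnRule("rel_sd", nonnegative=True),
        ColumnRule("seed", nonnegative=True),
    ],
    "titration": [
        ColumnRule("step_added", positive=True, increasing=True),
        ColumnRule("uptake", nonnegative=True),
        ColumnRule("supernatant", nonnegative=True),
        ColumnRule("shell_thickness_nm", nonnegative=True),
    ],
    "correlogram": [
        ColumnRule("tau_s", positive=True, increasing=True),
        ColumnRule("g2"),
    ],
    "measurements": [
        ColumnRule("height_nm"),
        ColumnRule("width1_nm"),
        ColumnRule("width2_nm"),
        ColumnRule("d_eq_nm"),
        ColumnRule("aspect"),
        ColumnRule("excluded", kind="text"),
        ColumnRule("reason", kind="text"),
    ],
    "fits": [
        ColumnRule("label", kind="text"),
        ColumnRule("median_nm", positive=True),
        ColumnRule("sigma_log", nonnegative=True),
        ColumnRule("mode_nm", positive=True),
        ColumnRule("n", positive=True),
    ],
    "dls_results": [
        ColumnRule("label", kind="text"),
        ColumnRule("z_average_nm", positive=True),
        ColumnRule("pdi"),
    ],
    "series_pair": [
        ColumnRule("label", kind="text"),
        ColumnRule("d_afm_nm", positive=True),
        ColumnRule("d_dls_nm", positive=True),
    ],
    "shell_estimate": [
        ColumnRule("thickness_nm"),
        ColumnRule("se_nm", nonnegative=True),
        ColumnRule("n_used", positive=True),
    ],
    "exclusions": [
        ColumnRule("label", kind="text"),
        ColumnRule("reason", kind="text"),
    ],
    "chemistry": [
        ColumnRule("quantity", kind="text"),
        ColumnRule("value"),
    ],
}


def validate_dataframe(df: pd.DataFrame, schema_name: str) -> list[str]:
    """Check a DataFrame against a registered schema; return diagnostics."""
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    diags: list[str] = []
    for rule in SCHEMAS[schema_name]:
        if rule.name not in df.columns:
            diags.append(f"missing column {rule.name!r}")
            continue
        col = df[rule.name]
        if rule.kind == "numeric":
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.isna() & col.notna()
            for idx in df.index[bad]:
                diags.append(f"column {rule.name!r} row {idx}: not numeric ({col[idx]!r})")
            if rule.positive:
                for idx in df.index[vals <= 0]:
                    diags.append(f"column {rule.name!r} row {idx}: must be > 0 "
                                 f"(got {vals[idx]})")
            elif rule.nonnegative:
                for idx in df.index[vals < 0]:
                    diags.append(f"column {rule.name!r} row {idx}: must be >= 0 "
                                 f"(got {vals[idx]})")
            if rule.increasing and vals.notna().all():
                arr = vals.to_numpy(float)
                for k in np.nonzero(np.diff(arr) <= 0)[0]:
                    diags.append(f"column {rule.name!r} row {df.index[k + 1]}: "
                                 "not strictly increasing")
    return diags


def validate_csv(path, schema_name: str) -> tuple[bool, list[str]]:
    """Validate a CSV file against a registered schema.

    Returns ``(ok, diagnostics)``; every violation names its column and row.
    """
    path = Path(path)
    if not path.exists():
        return False, [f"{path}: file not found"]
    df = pd.read_csv(path)
    diags = validate_dataframe(df, schema_name)
    return (not diags), [f"{path.name}: {d}" for d in diags]
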