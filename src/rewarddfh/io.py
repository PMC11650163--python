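"""Reading and writing the pipeline's tables and result bundles.

Canonical on-disk table format is TSV (UTF-8, '.' decimal) because atlas
region labels can contain commas; CSV is accepted on read (delimiter chosen
by file extension). Results (hyperplane, norm reference, feature selection,
statistical tests) are JSON with sorted keys so identical runs produce
identical bytes.

Validation is strict and total: malformed inputs raise
:class:`~rewarddfh.errors.ValidationError` naming the offending subject or
column, never silently dropping rows. Missing phenotype scale values are
permitted (empty fields -> NaN) and propagate to pairwise-complete
statistics downstream.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic import CONDITIONS, DIAGNOSES, SCALE_COLUMNS

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "validate_feature_table",
    "validate_phenotype_table",
    "write_json",
    "read_json",
    "write_results",
]

GROUPS = ("TD_train", "TD_test", "clinical")

# published scoring ranges used for the out-of-range warning on read
_SCALE_RANGES = {
    "SDQ-CP": (0, 10), "RPAQ-Reactive": (0, 22), "RPAQ-Proactive": (0, 24),
    "Conners-ADHD": (0, 30), "SDQ-Hyperactivity": (0, 10), "SDQ-Emotional": (0, 10),
    "CDI": (0, 54), "SCARED-Total": (0, 82), "SCARED-GAD": (0, 18),
    "CTQ-Abuse": (15, 75), "CTQ-Neglect": (10, 50), "AUDIT": (0, 40),
    "CUDIT": (0, 40), "ICU": (0, 72), "ARI": (0, 12),
}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def validate_feature_table(
    table: pd.DataFrame, expected_regions=None
) -> pd.DataFrame:
    """Enforce the feature-table contract.

    Exactly two rows per subject (one per condition), known condition
    labels, no missing cells, at least one region column. If
    ``expected_regions`` is given, unexpected extra columns are warned
    about but carried through; missing expected regions are an error.
    """
    required = ["subject_id", "condition"]
    for col in required:
        if col not in table.columns:
            raise ValidationError(f"feature table missing required column {col!r}")
    region_cols = [c for c in table.columns if c not in required]
    if not region_cols:
        raise ValidationError("feature table has no region columns")
    if expected_regions is not None:
        expected = list(expected_regions)
        absent = sorted(set(expected) - set(region_cols))
        if absent:
            raise ValidationError(f"expected region columns missing: {absent[:10]}")
        extra = [c for c in region_cols if c not in set(expected)]
        if extra:
            warnings.warn(
                f"unexpected extra column(s) carried through: {extra[:10]}",
                stacklevel=2,
            )

    bad = set(table["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition label(s): {sorted(bad)}")

    dup = table.duplicated(subset=["subject_id", "condition"])
    if dup.any():
        pairs = table.loc[dup, ["subject_id", "condition"]].itertuples(index=False)
        raise ValidationError(
            "duplicate (subject, condition) rows: "
            + ", ".join(f"({s}, {c})" for s, c in pairs)
        )

    counts = table.groupby("subject_id", sort=False)["condition"].count()
    incomplete = counts[counts != 2]
    if len(incomplete):
        raise ValidationError(
            "subjects without both condition rows: "
            + ", ".join(str(s) for s in incomplete.index[:10])
        )

    vals = table[region_cols]
    if vals.isna().any().any():
        bad_cols = vals.columns[vals.isna().any()].tolist()
        raise ValidationError(f"NaN feature values in columns: {bad_cols[:10]}")
    if not all(np.issubdtype(vals[c].dtype, np.number) for c in region_cols):
        non_num = [c for c in region_cols if not np.issubdtype(vals[c].dtype, np.number)]
        raise ValidationError(f"non-numeric region columns: {non_num[:10]}")
    return table


def read_feature_table(path: str | Path, expected_regions=None) -> pd.DataFrame:
    """Read and validate a feature table (TSV canonical, CSV accepted)."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    if list(table.columns[:2]) != ["subject_id", "condition"]:
        raise ValidationError(
            f"{path.name}: first two columns must be subject_id, condition, "
            f"got {list(table.columns[:2])}"
        )
    return validate_feature_table(table, expected_regions=expected_regions)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_sep_for(path), index=False)
    return path


def validate_phenotype_table(
    table: pd.DataFrame, feature_subjects=None
) -> pd.DataFrame:
    """Enforce the phenotype-table contract; warn on out-of-range scores."""
    if "subject_id" not in table.columns:
        raise ValidationError("phenotype table missing subject_id column")
    dup = table["subject_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate subject_id: {table.loc[dup, 'subject_id'].tolist()[:10]}"
        )
    if "group" in table.columns:
        bad = set(table["group"].dropna()) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
    if feature_subjects is not None:
        missing = set(feature_subjects) - set(table["subject_id"])
        if missing:
            raise ValidationError(
                f"feature-table subjects absent from phenotypes: {sorted(missing)[:10]}"
            )
    for scale, (lo, hi) in _SCALE_RANGES.items():
        if scale in table.columns:
            vals = pd.to_numeric(table[scale], errors="coerce")
            out = vals.notna() & ((vals < lo) | (vals > hi))
            if out.any():
                warnings.warn(
                    f"{scale}: {int(out.sum())} value(s) outside [{lo}, {hi}]; kept",
                    stacklevel=2,
                )
    return table


def read_phenotype_table(
    path: str | Path, feature_subjects=None
) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    for d in DIAGNOSES:
        if d in table.columns and table[d].dtype != bool:
            table[d] = (
                table[d].astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
            )
    for scale in SCALE_COLUMNS:
        if scale in table.columns:
            table[scale] = pd.to_numeric(table[scale], errors="coerce")
    return validate_phenotype_table(table, feature_subjects=feature_subjects)


def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_sep_for(path), index=False)
    return path


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n"
    )
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_results(bundle: Mapping[str, Mapping], out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle of result dictionaries as one JSON file each.

    Keys of ``bundle`` become file stems; deterministic key order inside
    each file. Returns the written paths keyed by bundle entry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {
        name: write_json(payload, out_dir / f"{name}.json")
        for name, payload in bundle.items()
    }
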