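"""Peak-table CSV dialect (El-MAVEN-export style) and sample metadata.

A peak table has the columns ``compound, formula, isotopeLabel`` followed
by one numeric intensity column per sample.  Isotope label tags follow the
export grammar:

* ``C12 PARENT``   -- the unlabeled M+0 isotopologue (any tracer)
* ``C13-label-k``  -- M+k under a 13C tracer
* ``D-label-k``    -- M+k under a 2H tracer

Sample metadata (group, mouse pairing, serum tracer enrichment) lives in a
sidecar CSV with columns ``sample, group, mouse_id, serum_enrichment``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARENT_TAG",
    "parse_label",
    "format_label",
    "CompoundTable",
    "PeakTable",
    "read_peak_table",
    "write_peak_table",
    "read_sample_metadata",
]

PARENT_TAG = "C12 PARENT"
_LABEL_RE = re.compile(r"^(C13|D)-label-([0-9]+)$")
_TAG_ELEMENT = {"C13": "C", "D": "H"}


def parse_label(tag: str) -> tuple[str | None, int]:
    """Parse an isotope label tag into (tracer element, mass shift).

    The parent tag carries no tracer element (returns ``(None, 0)``).
    """
    tag = tag.strip()
    if tag == PARENT_TAG:
        return None, 0
    m = _LABEL_RE.match(tag)
    if m is None:
        raise ValueError(f"unknown isotope label tag {tag!r}")
    shift = int(m.group(2))
    if shift < 1:
        raise ValueError(f"label tag {tag!r} must have shift >= 1")
    return _TAG_ELEMENT[m.group(1)], shift


def format_label(element: str, shift: int) -> str:
    if shift == 0:
        return PARENT_TAG
    prefix = {"C": "C13", "H": "D"}.get(element)
    if prefix is None:
        raise ValueError(f"no label tag for tracer element {element!r}")
    return f"{prefix}-label-{shift}"


@dataclass
class CompoundTable:
    """Ordered raw intensity vectors for one compound.

    ``intensities`` is indexed by mass shift 0..max observed and has one
    column per sample; shifts absent from the file are zero-filled.
    """

    name: str
    formula: str
    element: str | None
    intensities: pd.DataFrame

    @property
    def n_shifts(self) -> int:
        return int(self.intensities.index.max())

    def raw_vector(self, sample: str) -> np.ndarray:
        return self.intensities[sample].to_numpy(dtype=float)


@dataclass
class PeakTable:
    samples: list[str]
    compounds: dict[str, CompoundTable]


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peak-table CSV, validating tags, shifts and intensities."""
    df = pd.read_csv(path)
    required = ["compound", "formula", "isotopeLabel"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} is missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ValueError(f"peak table {path} has no sample columns")
    if df.empty:
        raise ValueError(f"peak table {path} contains no rows")

    compounds: dict[str, CompoundTable] = {}
    for name, block in df.groupby("compound", sort=False):
        formulas = block["formula"].unique()
        if len(formulas) != 1:
            raise ValueError(f"compound {name!r} has conflicting formulas {list(formulas)}")
        element: str | None = None
        seen: dict[int, np.ndarray] = {}
        for _, row in block.iterrows():
            el, shift = parse_label(str(row["isotopeLabel"]))
            if el is not None:
                if element is not None and el != element:
                    raise ValueError(f"compound {name!r} mixes tracer elements {element} and {el}")
                element = el
            if shift in seen:
                raise ValueError(f"duplicate isotopologue shift {shift} for compound {name!r}")
            values = pd.to_numeric(row[sample_cols], errors="coerce")
            bad = row[sample_cols][values.isna() & row[sample_cols].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric intensity for compound {name!r} shift {shift}: {dict(bad)}"
                )
            vec = values.to_numpy(dtype=float)
            if np.nansum(vec < 0):
                raise ValueError(f"negative intensity for compound {name!r} shift {shift}")
            seen[shift] = np.nan_to_num(vec, nan=0.0)
        max_shift = max(seen)
        matrix = np.zeros((max_shift + 1, len(sample_cols)))
        missing_shifts = []
        for shift in range(max_shift + 1):
            if shift in seen:
                matrix[shift] = seen[shift]
            else:
                missing_shifts.append(shift)
        if missing_shifts:
            warnings.warn(
                f"compound {name!r}: missing isotopologue rows at shifts {missing_shifts}; "
                "treated as intensity 0",
                stacklevel=2,
            )
        compounds[str(name)] = CompoundTable(
            name=str(name),
            formula=str(formulas[0]),
            element=element,
            intensities=pd.DataFrame(matrix, index=range(max_shift + 1), columns=sample_cols),
        )
    return PeakTable(samples=sample_cols, compounds=compounds)


def write_peak_table(
    path: str | Path,
    compounds: Sequence[tuple[str, str, str, np.ndarray]],
    samples: Sequence[str],
) -> None:
    """Write compounds as a peak-table CSV.

    Each entry of ``compounds`` is ``(name, formula, tracer_element,
    matrix)`` with ``matrix`` of shape (n_shifts + 1, n_samples).
    """
    rows = []
    for name, formula, element, matrix in compounds:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[1] != len(samples):
            raise ValueError(f"compound {name!r}: matrix has {matrix.shape[1]} columns, expected {len(samples)}")
        for shift in range(matrix.shape[0]):
            row = {"compound": name, "formula": formula, "isotopeLabel": format_label(element, shift)}
            row.update({s: matrix[shift, i] for i, s in enumerate(samples)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar sample table, indexed by sample name."""
    df = pd.read_csv(path)
    required = ["sample", "group", "mouse_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample metadata {path} is missing columns {missing}")
    if df["sample"].duplicated().any():
        raise ValueError(f"sample metadata {path} has duplicate sample names")
    return df.set_index("sample")
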