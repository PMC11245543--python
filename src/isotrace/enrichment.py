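"""Labeling metrics computed from corrected MIDs.

Two summary statistics are reported side by side for every corrected MID,
because plotted "labeling fraction" values in the tracing literature can
mean either:

* ``labeled_fraction`` = 1 - m0, the fraction of molecules carrying at
  least one tracer atom;
* ``fractional_enrichment`` = sum(i * m_i) / n_atoms, the atom-weighted
  fraction of label-capable positions that carry label.

For in-vivo 13C-glucose data, tumor metabolite labeling is normalized to
the serum tracer enrichment of the same mouse, which removes mouse-to-mouse
variation in how enriched circulating glucose became during the infusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import as_mid, parse_formula

__all__ = [
    "LabelingResult",
    "NormalizedEnrichment",
    "FattyAcidLabeling",
    "FATTY_ACID_FORMULAS",
    "ESSENTIAL_FATTY_ACIDS",
    "labeling_metrics",
    "normalize_to_serum",
    "serum_glucose_enrichment",
    "fatty_acid_labeling",
]


@dataclass(frozen=True)
class LabelingResult:
    labeled_fraction: float
    fractional_enrichment: float
    n_atoms: int


@dataclass(frozen=True)
class NormalizedEnrichment:
    """Tumor labeling divided by the same mouse's serum tracer enrichment.

    The value may exceed 1 (e.g. multi-carbon metabolites downstream of a
    partially labeled precursor pool are compared to a per-molecule serum
    metric); the denominator is recorded for traceability.
    """

    value: float
    mouse_id: str | None
    serum_enrichment: float


@dataclass(frozen=True)
class FattyAcidLabeling:
    """Labeling metrics for one saponified fatty acid."""

    name: str
    essential: bool
    labeled_fraction: float
    fractional_enrichment: float
    n_atoms: int


#: Free (saponified) fatty acid formulas keyed by chain:double-bond name.
FATTY_ACID_FORMULAS = {
    "C14:0": "C14H28O2",
    "C16:0": "C16H32O2",
    "C16:1": "C16H30O2",
    "C18:0": "C18H36O2",
    "C18:1": "C18H34O2",
    "C18:2": "C18H32O2",
    "C18:3": "C18H30O2",
}

#: Dietary-only fatty acids; their labeling is a built-in zero control.
ESSENTIAL_FATTY_ACIDS = frozenset({"C18:2", "C18:3"})


def labeling_metrics(mid: Sequence[float], n_atoms: int) -> LabelingResult:
    """Labeled fraction (1 - m0) and atom-weighted fractional enrichment."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    vec = as_mid(mid)
    labeled = float(1.0 - vec[0])
    enrichment = float(np.arange(vec.size) @ vec / n_atoms)
    return LabelingResult(labeled_fraction=labeled, fractional_enrichment=enrichment, n_atoms=n_atoms)


def normalize_to_serum(
    tumor_metric: float,
    serum_tracer_enrichment: float,
    mouse_id: str | None = None,
) -> NormalizedEnrichment:
    """Divide a tumor labeling metric by the mouse-matched serum enrichment."""
    if not np.isfinite(serum_tracer_enrichment) or serum_tracer_enrichment <= 0:
        raise ValueError("serum tracer enrichment must be > 0")
    if tumor_metric < 0:
        raise ValueError("tumor labeling metric must be >= 0")
    return NormalizedEnrichment(
        value=tumor_metric / serum_tracer_enrichment,
        mouse_id=mouse_id,
        serum_enrichment=serum_tracer_enrichment,
    )


def serum_glucose_enrichment(mid: Sequence[float], method: str = "atom_fraction") -> float:
    """Serum [U-13C6]-glucose enrichment from its corrected MID.

    ``atom_fraction`` (default) returns sum(i * m_i) / 6; ``m6`` returns
    the fully labeled M+6 fraction.  Both conventions appear in the
    tracing literature, so the choice is explicit here.
    """
    vec = as_mid(mid)
    if method == "atom_fraction":
        return float(np.arange(vec.size) @ vec / 6.0)
    if method == "m6":
        return float(vec[6]) if vec.size > 6 else 0.0
    raise ValueError(f"unknown serum enrichment method {method!r}")


def fatty_acid_labeling(
    mid: Sequence[float],
    name: str,
    formula: str | None = None,
    element: str = "H",
    essential: bool | None = None,
) -> FattyAcidLabeling:
    """Labeling metrics for a saponified fatty acid.

    ``n_atoms`` is the hydrogen count of the free fatty acid for 2H (D2O)
    data, or the carbon count for 13C data.  The essential flag is carried
    through for reporting only; essential fatty acids cannot be made de
    novo, so their labeling is expected to sit at the noise floor.
    """
    formula_str = formula or FATTY_ACID_FORMULAS.get(name)
    if formula_str is None:
        raise ValueError(f"unknown fatty acid {name!r}: provide a formula")
    parsed = parse_formula(formula_str)
    n_atoms = parsed.get(element)
    if n_atoms < 1:
        raise ValueError(f"fatty acid {name!r} has no {element} atoms")
    if essential is None:
        essential = name in ESSENTIAL_FATTY_ACIDS
    base = labeling_metrics(mid, n_atoms)
    return FattyAcidLabeling(
        name=name,
        essential=bool(essential),
        labeled_fraction=base.labeled_fraction,
        fractional_enrichment=base.fractional_enrichment,
        n_atoms=n_atoms,
    )
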