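"""Forward simulation of a WT/KO tracing cohort with known ground truth.

The generator emulates the measurements of an in-vivo/in-vitro isotope
tracing study of oxPPP-deficient (G6PD-knockout) versus wild-type tumors:

* tumor serine/glycine 13C labeling from [U-13C6]-glucose infusion, with a
  mouse-matched serum glucose enrichment table (KO tumors synthesize less
  serine from glucose);
* tumor serine 2H labeling from [2,3,3-2H]-serine infusion (KO tumors take
  up more serine);
* NADP+/NADPH 2H pairs linked by a ground-truth active-hydride labeling
  fraction p (higher in KO, where one-carbon metabolism supplies more of
  the NADPH hydride);
* saponified fatty-acid 2H labeling from D2O (newly synthesized fraction f
  with per-hydrogen incorporation probability q; zero for the essential
  fatty acid C18:2, the internal negative control);
* bench-assay tables (serine consumption time course, ROS, redox pools,
  confluence) with the KO effect directions of the study design.

True MIDs are binomial in the per-atom enrichment.  Measurement noise is
multiplicative lognormal on raw intensities -- where noise physically
enters -- applied after forward convolution through the same correction
matrix the analysis inverts.  Per-sample intensity scales are drawn
log-uniformly over 1e5-1e8 so that scale invariance is exercised.
All randomness flows from a single seed; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .chem import ElementalFormula, IsotopeTable, as_mid, parse_formula
from .correction import TracerSpec, build_correction_matrix
from .io import write_peak_table

__all__ = [
    "GroupSpec",
    "SimConfig",
    "CohortPaths",
    "default_groups",
    "NADP_FORMULA",
    "NADPH_FORMULA",
    "simulate_true_mid",
    "simulate_measurement",
    "simulate_nadph_pair",
    "simulate_fatty_acid_mid",
    "simulate_cohort",
]

NADP_FORMULA = "C21H28N7O17P3"
NADPH_FORMULA = "C21H29N7O17P3"

_FRACTION_FIELDS = (
    "p_active_h",
    "serum_enrichment",
    "serine_c13_enrichment",
    "serine_h2_enrichment",
    "fa_new_fraction",
    "fa_h2_incorporation",
    "nadp_background_enrichment",
)


@dataclass(frozen=True)
class GroupSpec:
    """Ground-truth parameters for one cohort arm.

    Fractions are per-atom enrichments or molecule fractions in [0, 1];
    assay-level expectations are the noise-free well values.
    """

    name: str
    p_active_h: float
    serum_enrichment: float
    serine_c13_enrichment: float
    serine_h2_enrichment: float
    fa_new_fraction: float
    fa_h2_incorporation: float
    nadp_background_enrichment: float = 0.05
    serine_consumption_ug_per_1e6: float = 15.0
    ros_au_per_1e6: float = 3000.0
    nadph_nadp_ratio: float = 1.2
    gsh_gssg_ratio: float = 12.0
    confluence_slope_pct_per_h: float = 0.9
    cells_seeded: float = 5e4
    doubling_time_h: float = 20.0

    def __post_init__(self) -> None:
        for name in _FRACTION_FIELDS:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


def default_groups() -> tuple[GroupSpec, GroupSpec]:
    """The study conditions: WT versus G6PD-KO effect directions.

    KO tumors make less serine from glucose, take up more serine, draw
    more NADPH hydride from serine one-carbon flux, and synthesize fewer
    fatty acids de novo; KO cells grow slower, consume more serine per new
    cell, carry more ROS and a weaker redox poise.
    """
    wt = GroupSpec(
        name="WT",
        p_active_h=0.05,
        serum_enrichment=0.40,
        serine_c13_enrichment=0.15,
        serine_h2_enrichment=0.10,
        fa_new_fraction=0.25,
        fa_h2_incorporation=0.045,
        serine_consumption_ug_per_1e6=15.0,
        ros_au_per_1e6=3000.0,
        nadph_nadp_ratio=1.2,
        gsh_gssg_ratio=12.0,
        confluence_slope_pct_per_h=0.9,
        cells_seeded=5e4,
        doubling_time_h=20.0,
    )
    ko = GroupSpec(
        name="KO",
        p_active_h=0.15,
        serum_enrichment=0.40,
        serine_c13_enrichment=0.08,
        serine_h2_enrichment=0.20,
        fa_new_fraction=0.10,
        fa_h2_incorporation=0.045,
        serine_consumption_ug_per_1e6=25.0,
        ros_au_per_1e6=6000.0,
        nadph_nadp_ratio=0.6,
        gsh_gssg_ratio=5.0,
        confluence_slope_pct_per_h=0.5,
        cells_seeded=1e5,
        doubling_time_h=30.0,
    )
    return wt, ko


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_per_group: int = 8
    groups: tuple[GroupSpec, ...] = field(default_factory=default_groups)
    noise_cv: float = 0.02
    tracer_purity: float = 0.99
    mode: str = "high_res"
    scale_range: tuple[float, float] = (1e5, 1e8)
    fa_zero_synthesis: tuple[str, ...] = ("C18:2",)

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0.0 < self.tracer_purity <= 1.0):
            raise ValueError("tracer_purity must be in (0, 1]")
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass(frozen=True)
class CohortPaths:
    """Files emitted by :func:`simulate_cohort`."""

    outdir: Path
    samples: Path
    peaks_serine_c13: Path
    peaks_serine_h2: Path
    peaks_nadph_h2: Path
    peaks_fatty_acids_h2: Path
    assay_serine_consumption: Path
    assay_ros: Path
    assay_redox: Path
    assay_confluence: Path
    ground_truth: Path
    config_echo: Path
    pipeline_config: Path

    def all_files(self) -> list[Path]:
        return [p for f, p in dataclasses.asdict(self).items() if f != "outdir"]


def simulate_true_mid(n_atoms: int, enrichment: float, model: str = "binomial") -> np.ndarray:
    """True (pre-convolution) MID for n label-capable atoms at a per-atom enrichment."""
    if model != "binomial":
        raise ValueError(f"unknown labeling model {model!r}")
    if not (0.0 <= enrichment <= 1.0):
        raise ValueError("enrichment must be in [0, 1]")
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return binom.pmf(np.arange(n_atoms + 1), n_atoms, enrichment)


def simulate_fatty_acid_mid(n_hydrogens: int, new_fraction: float, incorporation: float) -> np.ndarray:
    """2H MID of a fatty-acid pool: (1 - f) unlabeled + f newly synthesized.

    Newly synthesized molecules incorporate deuterium independently at each
    of the ``n_hydrogens`` positions with probability ``incorporation``.
    """
    if not (0.0 <= new_fraction <= 1.0):
        raise ValueError("new_fraction must be in [0, 1]")
    old = np.zeros(n_hydrogens + 1)
    old[0] = 1.0
    new = simulate_true_mid(n_hydrogens, incorporation)
    return (1.0 - new_fraction) * old + new_fraction * new


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_measurement(
    true_mid: Sequence[float],
    formula: ElementalFormula,
    tracer: TracerSpec,
    noise_cv: float,
    rng: np.random.Generator,
    mode: str = "high_res",
    isotopes: IsotopeTable | None = None,
    scale: float | None = None,
    scale_range: tuple[float, float] = (1e5, 1e8),
) -> np.ndarray:
    """Raw intensities: scale * (CorrectionMatrix @ true_mid) * lognormal noise."""
    vec = as_mid(true_mid)
    if vec.size != tracer.n_label_atoms + 1:
        raise ValueError(
            f"true MID has {vec.size} entries; expected n_label_atoms + 1 = {tracer.n_label_atoms + 1}"
        )
    matrix = build_correction_matrix(formula, tracer, mode=mode, max_shift=tracer.n_label_atoms, isotopes=isotopes)
    expected = matrix.entries @ vec
    if scale is None:
        lo, hi = scale_range
        scale = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return scale * expected * _noise_factors(rng, noise_cv, expected.size)


def simulate_nadph_pair(
    nadp_true_mid: Sequence[float],
    p: float,
    noise_cv: float,
    rng: np.random.Generator,
    purity: float = 0.99,
    mode: str = "high_res",
    isotopes: IsotopeTable | None = None,
    scale_range: tuple[float, float] = (1e5, 1e8),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw NADP+ and NADPH intensity vectors for an active-H fraction p.

    Returns ``(nadp_raw, nadph_raw, nadph_true)`` where ``nadph_true`` is
    the mixture (1 - p) * [nadp; 0] + p * [0; nadp].
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    nadp_true = as_mid(nadp_true_mid)
    nadph_true = (1.0 - p) * np.concatenate([nadp_true, [0.0]]) + p * np.concatenate([[0.0], nadp_true])
    n = nadp_true.size - 1
    nadp_raw = simulate_measurement(
        nadp_true, parse_formula(NADP_FORMULA), TracerSpec("H", max(n, 1), purity),
        noise_cv, rng, mode, isotopes, scale_range=scale_range,
    )
    nadph_raw = simulate_measurement(
        nadph_true, parse_formula(NADPH_FORMULA), TracerSpec("H", n + 1, purity),
        noise_cv, rng, mode, isotopes, scale_range=scale_range,
    )
    return nadp_raw, nadph_raw, nadph_true


def _write_pipeline_config(paths: CohortPaths, config: SimConfig) -> None:
    """Emit a TOML config so the pipeline can consume the cohort directly."""
    essential = ", ".join(f'"{n}"' for n in ("C18:2", "C18:3"))
    text = f"""# auto-generated by isotrace simulate
[run]
output_dir = "pipeline_out"
seed = {config.seed}
mode = "{config.mode}"

[samples]
metadata = "{paths.samples.name}"

[tracks.serine_c13]
kind = "labeling"
peak_table = "{paths.peaks_serine_c13.name}"
tracer_element = "C"
tracer_purity = {config.tracer_purity}
normalize_to_serum = true

[tracks.serine_h2]
kind = "labeling"
peak_table = "{paths.peaks_serine_h2.name}"
tracer_element = "H"
tracer_purity = {config.tracer_purity}

[tracks.nadph]
kind = "nadph"
peak_table = "{paths.peaks_nadph_h2.name}"
tracer_element = "H"
tracer_purity = {config.tracer_purity}
nadp_compound = "NADP+"
nadph_compound = "NADPH"

[tracks.fatty_acids]
kind = "fatty_acid"
peak_table = "{paths.peaks_fatty_acids_h2.name}"
tracer_element = "H"
tracer_purity = {config.tracer_purity}
essential = [{essential}]

[assays]
serine_consumption = "{paths.assay_serine_consumption.name}"
ros = "{paths.assay_ros.name}"
redox = "{paths.assay_redox.name}"
confluence = "{paths.assay_confluence.name}"
"""
    paths.pipeline_config.write_text(text)


def simulate_cohort(config: SimConfig, outdir: str | Path) -> CohortPaths:
    """Emit peak tables, assay tables, metadata and ground truth for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    samples: list[str] = []
    sample_group: list[GroupSpec] = []
    for group in config.groups:
        for i in range(config.n_per_group):
            samples.append(f"{group.name}_{i + 1}")
            sample_group.append(group)

    paths = CohortPaths(
        outdir=outdir,
        samples=outdir / "samples.csv",
        peaks_serine_c13=outdir / "peaks_serine_c13.csv",
        peaks_serine_h2=outdir / "peaks_serine_h2.csv",
        peaks_nadph_h2=outdir / "peaks_nadph_h2.csv",
        peaks_fatty_acids_h2=outdir / "peaks_fatty_acids_h2.csv",
        assay_serine_consumption=outdir / "assay_serine_consumption.csv",
        assay_ros=outdir / "assay_ros.csv",
        assay_redox=outdir / "assay_redox.csv",
        assay_confluence=outdir / "assay_confluence.csv",
        ground_truth=outdir / "ground_truth.csv",
        config_echo=outdir / "config_echo.json",
        pipeline_config=outdir / "pipeline_config.toml",
    )

    # sample metadata (mouse pairing key = sample; serum enrichment per mouse)
    pd.DataFrame(
        {
            "sample": samples,
            "group": [g.name for g in sample_group],
            "mouse_id": samples,
            "serum_enrichment": [g.serum_enrichment for g in sample_group],
        }
    ).to_csv(paths.samples, index=False)

    def per_sample_matrix(true_for_group, formula: str, element: str) -> np.ndarray:
        tracer_n = {g.name: true_for_group(g).size - 1 for g in config.groups}
        n = max(tracer_n.values())
        cols = []
        for g in sample_group:
            true_mid = true_for_group(g)
            tracer = TracerSpec(element, true_mid.size - 1, config.tracer_purity)
            raw = simulate_measurement(
                true_mid, parse_formula(formula), tracer, config.noise_cv, rng,
                config.mode, scale_range=config.scale_range,
            )
            cols.append(np.pad(raw, (0, n + 1 - raw.size)))
        return np.column_stack(cols)

    # 13C-glucose track: tumor serine + glycine
    write_peak_table(
        paths.peaks_serine_c13,
        [
            ("serine", "C3H7NO3", "C",
             per_sample_matrix(lambda g: simulate_true_mid(3, g.serine_c13_enrichment), "C3H7NO3", "C")),
            ("glycine", "C2H5NO2", "C",
             per_sample_matrix(lambda g: simulate_true_mid(2, g.serine_c13_enrichment), "C2H5NO2", "C")),
        ],
        samples,
    )

    # 2H-serine track: tumor serine (three deuterated positions)
    write_peak_table(
        paths.peaks_serine_h2,
        [
            ("serine", "C3H7NO3", "H",
             per_sample_matrix(lambda g: simulate_true_mid(3, g.serine_h2_enrichment), "C3H7NO3", "H")),
        ],
        samples,
    )

    # NADP+/NADPH pair track
    nadp_cols, nadph_cols = [], []
    true_p = []
    for g in sample_group:
        nadp_true = simulate_true_mid(2, g.nadp_background_enrichment)
        nadp_raw, nadph_raw, _ = simulate_nadph_pair(
            nadp_true, g.p_active_h, config.noise_cv, rng,
            purity=config.tracer_purity, mode=config.mode, scale_range=config.scale_range,
        )
        nadp_cols.append(np.pad(nadp_raw, (0, 1)))  # pad NADP+ to the NADPH length
        nadph_cols.append(nadph_raw)
        true_p.append(g.p_active_h)
    write_peak_table(
        paths.peaks_nadph_h2,
        [
            ("NADP+", NADP_FORMULA, "H", np.column_stack(nadp_cols)),
            ("NADPH", NADPH_FORMULA, "H", np.column_stack(nadph_cols)),
        ],
        samples,
    )

    # D2O fatty-acid track: C16:0 (de novo synthesis) and C18:2 (essential, zero)
    def fa_true(g: GroupSpec, name: str, n_h: int) -> np.ndarray:
        f = 0.0 if name in config.fa_zero_synthesis else g.fa_new_fraction
        return simulate_fatty_acid_mid(n_h, f, g.fa_h2_incorporation)

    write_peak_table(
        paths.peaks_fatty_acids_h2,
        [
            ("C16:0", "C16H32O2", "H",
             per_sample_matrix(lambda g: fa_true(g, "C16:0", 32), "C16H32O2", "H")),
            ("C18:2", "C18H32O2", "H",
             per_sample_matrix(lambda g: fa_true(g, "C18:2", 32), "C18H32O2", "H")),
        ],
        samples,
    )

    # bench assays: two wells per timepoint, per group (cell-line level);
    # 24-well format, 1 mL of medium at 30 mg/L serine = 30 ug at 0 h
    amount_t0 = 30.0
    consumption_rows = []
    for g in config.groups:
        for t in (24.0, 36.0, 48.0, 60.0):
            for well in (1, 2):
                cells_t = g.cells_seeded * 2 ** (t / g.doubling_time_h)
                consumed = g.serine_consumption_ug_per_1e6 * (cells_t - g.cells_seeded) / 1e6
                amount_t = (amount_t0 - consumed) * _noise_factors(rng, config.noise_cv, 1)[0]
                consumption_rows.append(
                    {
                        "group": g.name, "well": well, "timepoint_h": t,
                        "amount_t0_ug": amount_t0, "amount_t_ug": amount_t,
                        "cells_t0": g.cells_seeded, "cells_t": cells_t,
                    }
                )
    pd.DataFrame(consumption_rows).to_csv(paths.assay_serine_consumption, index=False)

    ros_rows = []
    for g in config.groups:
        for well in (1, 2, 3):
            cells_m = 0.5 * _noise_factors(rng, config.noise_cv, 1)[0]
            stained = 500.0 + g.ros_au_per_1e6 * cells_m * _noise_factors(rng, config.noise_cv, 1)[0]
            ros_rows.append(
                {
                    "group": g.name, "well": well,
                    "f_stained": stained, "f_unstained": 500.0, "cells_millions": cells_m,
                }
            )
    pd.DataFrame(ros_rows).to_csv(paths.assay_ros, index=False)

    redox_rows = []
    for g in config.groups:
        for well in (1, 2, 3, 4):
            noise = _noise_factors(rng, config.noise_cv, 4)
            redox_rows.append(
                {
                    "group": g.name, "well": well,
                    "nadph": 10.0 * g.nadph_nadp_ratio * noise[0],
                    "nadp": 10.0 * noise[1],
                    "gsh": 10.0 * g.gsh_gssg_ratio * noise[2],
                    "gssg": 10.0 * noise[3],
                }
            )
    pd.DataFrame(redox_rows).to_csv(paths.assay_redox, index=False)

    confluence_rows = []
    times = np.arange(0.0, 96.0 + 1e-9, 2.0)
    for g in config.groups:
        for well in (1, 2, 3):
            y = 5.0 + g.confluence_slope_pct_per_h * times + rng.normal(0.0, 0.3, times.size)
            for t, v in zip(times, y):
                confluence_rows.append(
                    {"group": g.name, "well": well, "time_h": t, "confluence_pct": v}
                )
    pd.DataFrame(confluence_rows).to_csv(paths.assay_confluence, index=False)

    # ground truth and config echo
    pd.DataFrame(
        {
            "sample": samples,
            "group": [g.name for g in sample_group],
            "p_active_h": true_p,
            "serum_enrichment": [g.serum_enrichment for g in sample_group],
            "serine_c13_enrichment": [g.serine_c13_enrichment for g in sample_group],
            "serine_h2_enrichment": [g.serine_h2_enrichment for g in sample_group],
            "fa_new_fraction": [g.fa_new_fraction for g in sample_group],
            "fa_h2_incorporation": [g.fa_h2_incorporation for g in sample_group],
        }
    ).to_csv(paths.ground_truth, index=False)
    paths.config_echo.write_text(json.dumps(dataclasses.asdict(config), indent=2, default=list) + "\n")

    _write_pipeline_config(paths, config)
    return paths
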