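"""Config-driven pipeline: correct -> labeling metrics -> track-specific readouts.

A run is described by a single TOML file naming the peak tables, tracer
specs and assay tables.  Three track kinds cover the analysis routes of a
tracer study:

``labeling``
    Correct each compound and report labeled fraction and fractional
    enrichment; optionally divide by the mouse-matched serum tracer
    enrichment from the sample metadata (in-vivo 13C-glucose data).
``nadph``
    Correct the NADP+/NADPH pair per sample and solve for the
    active-hydride labeling fraction p, with a per-group summary.
``fatty_acid``
    Like ``labeling`` but with n_atoms taken from the saponified
    fatty-acid formula and an essential-fatty-acid flag carried through.

Everything the run needs is validated before any computation; outputs are
tidy CSVs plus a run log (versions, seed, config hash -- no wall-clock
timestamp, so reruns on identical inputs are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import pandas as pd

from . import __version__
from .assays import (
    ConsumptionRecord,
    RatioRecord,
    RosRecord,
    proliferation_slope,
    redox_ratio,
    ros_level,
    serine_consumption,
)
from .chem import IsotopeTable, parse_formula
from .correction import TracerSpec, build_correction_matrix, correct_intensities
from .enrichment import ESSENTIAL_FATTY_ACIDS, labeling_metrics, normalize_to_serum
from .io import CompoundTable, PeakTable, read_peak_table, read_sample_metadata
from .nadph import active_h_cohort

__all__ = ["run_pipeline", "correct_peak_table", "PipelineError"]


class PipelineError(RuntimeError):
    """Configuration or input problem detected before/while running."""


def _compound_tracer(
    compound: CompoundTable,
    tracer_element: str,
    purity: float,
    n_label_override: int | None = None,
) -> TracerSpec:
    """Tracer spec for one compound.

    The number of labelable atoms defaults to the smaller of the
    tracer-element count in the formula and the highest observed
    isotopologue shift: labeling beyond the measured shift range cannot be
    inferred, and positions beyond the labelable set cannot carry tracer.
    """
    element = compound.element or tracer_element
    formula = parse_formula(compound.formula)
    count = formula.get(element)
    if count < 1:
        raise PipelineError(
            f"compound {compound.name!r}: formula {compound.formula} has no {element} atoms"
        )
    n_label = n_label_override if n_label_override is not None else min(count, compound.n_shifts)
    if n_label < 1 or n_label > count:
        raise PipelineError(f"compound {compound.name!r}: invalid n_label_atoms {n_label}")
    return TracerSpec(element, n_label, purity)


def correct_peak_table(
    table: PeakTable,
    tracer_element: str,
    purity: float,
    mode: str = "high_res",
    isotopes: IsotopeTable | None = None,
    n_label_overrides: dict[str, int] | None = None,
) -> dict[str, dict[str, object]]:
    """Correct every compound x sample; returns nested {compound: {sample: CorrectedMID}}."""
    overrides = n_label_overrides or {}
    out: dict[str, dict[str, object]] = {}
    for name, compound in table.compounds.items():
        tracer = _compound_tracer(compound, tracer_element, purity, overrides.get(name))
        formula = parse_formula(compound.formula)
        matrix = build_correction_matrix(
            formula, tracer, mode=mode, max_shift=compound.n_shifts, isotopes=isotopes
        )
        out[name] = {
            sample: correct_intensities(compound.raw_vector(sample), matrix)
            for sample in table.samples
        }
    return out


def _corrected_frame(track: str, table: PeakTable, corrected) -> pd.DataFrame:
    rows = []
    for name, per_sample in corrected.items():
        for sample, cm in per_sample.items():
            for shift, frac in enumerate(cm.fractions):
                rows.append(
                    {
                        "track": track, "compound": name, "sample": sample,
                        "shift": shift, "fraction": frac,
                        "residual_norm": cm.residual_norm, "raw_total": cm.raw_total,
                    }
                )
    return pd.DataFrame(rows)


def _metrics_frame(track: str, table: PeakTable, corrected, tracer_element, purity, overrides, essential=()):
    rows = []
    for name, per_sample in corrected.items():
        compound = table.compounds[name]
        tracer = _compound_tracer(compound, tracer_element, purity, (overrides or {}).get(name))
        for sample, cm in per_sample.items():
            metrics = labeling_metrics(cm.fractions, tracer.n_label_atoms)
            rows.append(
                {
                    "track": track, "compound": name, "sample": sample,
                    "n_atoms": metrics.n_atoms,
                    "labeled_fraction": metrics.labeled_fraction,
                    "fractional_enrichment": metrics.fractional_enrichment,
                    "essential": name in essential,
                }
            )
    return pd.DataFrame(rows)


def _resolve(base: Path, value: str) -> Path:
    path = Path(value)
    return path if path.is_absolute() else base / path


def run_pipeline(config_path: str | Path) -> Path:
    """Execute every track and assay in the config; returns the output directory."""
    config_path = Path(config_path)
    base = config_path.parent
    raw_bytes = config_path.read_bytes()
    try:
        config = tomllib.loads(raw_bytes.decode("utf-8"))
    except tomllib.TOMLDecodeError as exc:
        raise PipelineError(f"cannot parse config {config_path}: {exc}") from exc

    run = config.get("run", {})
    outdir = _resolve(base, str(run.get("output_dir", "pipeline_out")))
    mode = str(run.get("mode", "high_res"))
    seed = int(run.get("seed", 0))
    isotope_csv = run.get("isotope_table")
    isotopes = IsotopeTable.from_csv(_resolve(base, isotope_csv)) if isotope_csv else None

    tracks = config.get("tracks", {})
    if not isinstance(tracks, dict) or not tracks:
        raise PipelineError("config defines no [tracks.*] sections")

    metadata = None
    samples_cfg = config.get("samples", {})
    if samples_cfg.get("metadata"):
        meta_path = _resolve(base, samples_cfg["metadata"])
        if not meta_path.exists():
            raise PipelineError(f"sample metadata not found: {meta_path}")
        metadata = read_sample_metadata(meta_path)

    # validate everything before computing anything
    for name, track in tracks.items():
        kind = track.get("kind")
        if kind not in ("labeling", "nadph", "fatty_acid"):
            raise PipelineError(f"track {name!r}: unknown kind {kind!r}")
        peak_path = _resolve(base, track.get("peak_table", ""))
        if not track.get("peak_table") or not peak_path.exists():
            raise PipelineError(f"track {name!r}: peak table not found: {peak_path}")
        if track.get("normalize_to_serum") and metadata is None:
            raise PipelineError(f"track {name!r}: normalize_to_serum needs sample metadata")
        if kind == "nadph" and not (track.get("nadp_compound") and track.get("nadph_compound")):
            raise PipelineError(f"track {name!r}: nadph track needs nadp_compound and nadph_compound")

    outdir.mkdir(parents=True, exist_ok=True)
    corrected_frames, metric_frames, normalized_frames = [], [], []
    active_frames, active_summaries = [], []

    for name, track in tracks.items():
        kind = track["kind"]
        table = read_peak_table(_resolve(base, track["peak_table"]))
        element = str(track.get("tracer_element", "C"))
        purity = float(track.get("tracer_purity", 1.0))
        overrides = {str(k): int(v) for k, v in track.get("n_label", {}).items()} or None
        corrected = correct_peak_table(table, element, purity, mode, isotopes, overrides)
        corrected_frames.append(_corrected_frame(name, table, corrected))

        if kind == "nadph":
            nadp_name = str(track["nadp_compound"])
            nadph_name = str(track["nadph_compound"])
            for needed in (nadp_name, nadph_name):
                if needed not in corrected:
                    raise PipelineError(f"track {name!r}: compound {needed!r} not in peak table")
            pairs = []
            for sample in table.samples:
                group = str(metadata.loc[sample, "group"]) if metadata is not None else "all"
                pairs.append(
                    (sample, group, corrected[nadp_name][sample].fractions,
                     corrected[nadph_name][sample].fractions)
                )
            per_sample, summary = active_h_cohort(pairs)
            per_sample.insert(0, "track", name)
            summary.insert(0, "track", name)
            active_frames.append(per_sample)
            active_summaries.append(summary)
            continue

        essential = set(track.get("essential", [])) if kind == "fatty_acid" else set()
        if kind == "fatty_acid" and not essential:
            essential = set(ESSENTIAL_FATTY_ACIDS)
        metrics = _metrics_frame(name, table, corrected, element, purity, overrides, essential)
        metric_frames.append(metrics)

        if track.get("normalize_to_serum"):
            rows = []
            for _, row in metrics.iterrows():
                sample = row["sample"]
                if sample not in metadata.index:
                    raise PipelineError(f"sample {sample!r} missing from metadata for normalization")
                serum = float(metadata.loc[sample, "serum_enrichment"])
                norm = normalize_to_serum(
                    row["labeled_fraction"], serum, str(metadata.loc[sample, "mouse_id"])
                )
                rows.append(
                    {
                        "track": name, "compound": row["compound"], "sample": sample,
                        "mouse_id": norm.mouse_id, "serum_enrichment": norm.serum_enrichment,
                        "normalized_value": norm.value,
                    }
                )
            normalized_frames.append(pd.DataFrame(rows))

    written: list[str] = []

    def emit(name: str, frames: list[pd.DataFrame]) -> None:
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(outdir / name, index=False)
            written.append(name)

    emit("corrected_mids.csv", corrected_frames)
    emit("labeling_metrics.csv", metric_frames)
    emit("normalized_enrichment.csv", normalized_frames)
    emit("active_h.csv", active_frames)
    emit("active_h_summary.csv", active_summaries)

    assays_cfg = config.get("assays", {})
    if assays_cfg:
        assay_df = compute_assays({k: _resolve(base, v) for k, v in assays_cfg.items()})
        assay_df.to_csv(outdir / "assays.csv", index=False)
        written.append("assays.csv")

    import numpy
    import scipy

    log = {
        "isotrace_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "mode": mode,
        "config_sha256": hashlib.sha256(raw_bytes).hexdigest(),
        "outputs": written,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return outdir


def compute_assays(paths: dict[str, Path]) -> pd.DataFrame:
    """Evaluate every configured bench assay into one tidy frame.

    Duplicate wells of the serine-consumption assay are combined by
    averaging the per-well consumption values within (group, timepoint).
    """
    rows = []
    if "serine_consumption" in paths:
        df = pd.read_csv(paths["serine_consumption"])
        per_well = df.assign(
            value=[
                serine_consumption(
                    ConsumptionRecord(
                        amount_t0=r.amount_t0_ug, amount_t=r.amount_t_ug,
                        cells_t0=r.cells_t0, cells_t=r.cells_t, timepoint=r.timepoint_h,
                    )
                )
                for r in df.itertuples()
            ]
        )
        for (group, t), sub in per_well.groupby(["group", "timepoint_h"]):
            rows.append(
                {
                    "assay": "serine_consumption", "group": group, "replicate": None,
                    "timepoint_h": t, "value": sub["value"].mean(),
                    "unit": "ug_per_1e6_cells",
                }
            )
    if "ros" in paths:
        df = pd.read_csv(paths["ros"])
        for r in df.itertuples():
            rows.append(
                {
                    "assay": "ros", "group": r.group, "replicate": r.well, "timepoint_h": None,
                    "value": ros_level(RosRecord(r.f_stained, r.f_unstained, r.cells_millions)),
                    "unit": "au_per_1e6_cells",
                }
            )
    if "redox" in paths:
        df = pd.read_csv(paths["redox"])
        for r in df.itertuples():
            for label, num, den in (("nadph_nadp_ratio", r.nadph, r.nadp), ("gsh_gssg_ratio", r.gsh, r.gssg)):
                rows.append(
                    {
                        "assay": label, "group": r.group, "replicate": r.well, "timepoint_h": None,
                        "value": redox_ratio(RatioRecord(num, den, label)), "unit": "ratio",
                    }
                )
    if "confluence" in paths:
        df = pd.read_csv(paths["confluence"])
        for (group, well), sub in df.groupby(["group", "well"]):
            sub = sub.sort_values("time_h")
            rows.append(
                {
                    "assay": "proliferation_slope", "group": group, "replicate": well,
                    "timepoint_h": None,
                    "value": proliferation_slope(sub["time_h"], sub["confluence_pct"]),
                    "unit": "pct_per_h",
                }
            )
    return pd.DataFrame(rows)
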