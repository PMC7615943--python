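"""Configuration-driven orchestration of the full reproducibility analysis.

The standard design extracts eight feature tables per cohort:

    {GUQ, IUQ} × {threshold on, off} × {merged, averaged dialect}

all at the same gray-level count, then compares the individual
quantizer against the global-quantizer reference per scan, per dialect,
per threshold state, and classifies each feature under the configured
cutoffs. For arms without thresholding, the global quantizer is
anchored to the cohort-global min/max over all in-mask voxels (computed
in a first pass), realizing "the same quantizer applied to every scan"
deterministically.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from .config import RunConfig, validate_config
from .errors import ConfigError
from .features import FeatureTable, extract_feature_table
from .image_io import Cohort, load_cohort_manifest, write_feature_table
from .phantom import generate_cohort
from .preprocess import ThresholdWindow, resample_isotropic
from .quantize import GUQ, IUQ, QuantizationSpec
from .reproducibility import (
    ComparisonKey,
    ReproducibilityReport,
    classify,
    compare_arms,
    feature_set_overlap,
)
from .texture import AVERAGED, MERGED

log = logging.getLogger("radrank")


def cohort_global_range(cohort: Cohort) -> tuple[float, float]:
    """min/max HU over all in-mask voxels of every scan in the cohort."""
    lo, hi = np.inf, -np.inf
    for case in cohort:
        for _, vol, mask in case.scans:
            vals = vol.data[mask.data]
            if vals.size:
                lo = min(lo, float(vals.min()))
                hi = max(hi, float(vals.max()))
    if not lo < hi:
        raise ConfigError("cohort intensities are constant; no global range")
    return lo, hi


def build_arm_specs(
    config: RunConfig, global_range: tuple[float, float]
) -> dict[tuple[str, bool], QuantizationSpec]:
    """Quantization specs keyed by (method, thresholded)."""
    windows = {
        True: ThresholdWindow(config.threshold_lo_hu, config.threshold_hi_hu, True),
        False: ThresholdWindow(config.threshold_lo_hu, config.threshold_hi_hu, False),
    }
    specs = {}
    for method in (GUQ, IUQ):
        for thresholded, window in windows.items():
            spec = QuantizationSpec(
                method=method, levels=config.levels, threshold=window
            )
            if method == GUQ and not thresholded:
                spec = spec.with_global_range(*global_range)
            specs[(method, thresholded)] = spec
    return specs


def extract_all_arms(
    cohort: Cohort, config: RunConfig
) -> dict[tuple[str, bool, str], FeatureTable]:
    """Feature tables for every (method, thresholded, dialect) arm."""
    specs = build_arm_specs(config, cohort_global_range(cohort))
    tables = {}
    for (method, thresholded), spec in specs.items():
        for dialect in (MERGED, AVERAGED):
            arm_id = f"{spec.arm_id}_{dialect}"
            log.info("extracting arm %s", arm_id)
            tables[(method, thresholded, dialect)] = extract_feature_table(
                cohort, spec, dialect=dialect, arm_id=arm_id
            )
    return tables


def compare_design(
    tables: dict[tuple[str, bool, str], FeatureTable], scan_ids: list[str]
) -> dict[ComparisonKey, list]:
    """IUQ-vs-GUQ comparisons per scan, dialect, and threshold state."""
    comparisons = {}
    for thresholded in (True, False):
        for dialect in (MERGED, AVERAGED):
            iuq = tables[(IUQ, thresholded, dialect)]
            guq = tables[(GUQ, thresholded, dialect)]
            for scan_id in scan_ids:
                key = ComparisonKey(thresholded, scan_id, dialect)
                comparisons[key] = compare_arms(
                    iuq.select_scan(scan_id), guq.select_scan(scan_id)
                )
    return comparisons


def load_cohort(config: RunConfig, seed: Optional[int] = None) -> Cohort:
    """Generate the phantom cohort (optionally reseeded) or load the manifest."""
    if config.manifest is not None:
        cohort = load_cohort_manifest(config.manifest)
        if config.resample_enabled:
            resampled = []
            for case in cohort:
                scans = []
                for scan_id, vol, mask in case.scans:
                    v, m = resample_isotropic(vol, mask, config.resample_spacing_mm)
                    scans.append((scan_id, v, m))
                resampled.append(dataclasses.replace(case, scans=scans))
            cohort = Cohort(cases=resampled)
        return cohort
    spec = config.phantom
    if seed is not None:
        spec = dataclasses.replace(spec, master_seed=int(seed))
    return generate_cohort(spec)


def retest_rs(
    cohort: Cohort, spec: QuantizationSpec, dialect: str = MERGED
) -> dict[str, float]:
    """Per-feature Spearman rs between scan 1 and scan 2 under one arm."""
    table = extract_feature_table(cohort, spec, dialect=dialect)
    scan_ids = cohort.scan_ids
    if len(scan_ids) != 2:
        raise ConfigError("retest_rs needs a two-scan cohort")
    comps = compare_arms(
        table.select_scan(scan_ids[0]), table.select_scan(scan_ids[1])
    )
    return {c.feature: c.rs for c in comps}


def retest_median_rs(
    phantom_spec, spec: Optional[QuantizationSpec] = None, dialect: str = MERGED
) -> float:
    """Median over the 43 features of the scan1-vs-scan2 rs on a fresh
    phantom cohort; the summary used to study retest-noise sensitivity."""
    cohort = generate_cohort(phantom_spec)
    rs = retest_rs(cohort, spec or QuantizationSpec(), dialect=dialect)
    vals = np.array(list(rs.values()), dtype=float)
    return float(np.nanmedian(vals))


def run(
    config: RunConfig,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> ReproducibilityReport:
    """Full pipeline: cohort → eight arm tables → comparisons → report files."""
    violations = validate_config(config)
    if violations:
        raise ConfigError("; ".join(violations))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = load_cohort(config, seed=seed)
    log.info("cohort: %d cases × %d scans", len(cohort), len(cohort.scan_ids))
    tables = extract_all_arms(cohort, config)
    for table in tables.values():
        write_feature_table(table, out / f"features_{table.arm_id}.csv")

    scan_ids = cohort.scan_ids
    if len(scan_ids) < 2:
        raise ConfigError(
            "the two-scan classification design needs test–retest cohorts; "
            "use compare_arms/ticked_features directly for single-scan data"
        )
    comparisons = compare_design(tables, scan_ids)
    report = classify(comparisons, cutoffs=config.cutoffs)
    report.to_json(out / "report.json")
    report.to_csv(out / "report.csv")

    venn_lines = []
    for c in report.cutoffs:
        part = feature_set_overlap(
            report.ticked(c, "with_threshold"), report.ticked(c, "without_threshold")
        )
        venn_lines.append(
            f"cutoff {c:g}: with_threshold_only={sorted(part.only_a)} "
            f"without_threshold_only={sorted(part.only_b)} both={sorted(part.both)}"
        )
    (out / "venn.txt").write_text("\n".join(venn_lines) + "\n")
    _write_log(out, config, seed, cohort, report)
    return report


def _write_log(out: Path, config: RunConfig, seed, cohort: Cohort, report) -> None:
    import radrank

    lines = [
        f"radrank {radrank.__version__}",
        f"numpy {np.__version__}",
        f"seed override: {seed}",
        f"config: {config}",
        f"cohort: {len(cohort)} cases, scans per case: {len(cohort.scan_ids)}",
    ]
    for c in report.cutoffs:
        frame = report.ticks[c]
        lines.append(
            f"cutoff {c:g}: with_threshold={int(frame['with_threshold'].sum())} "
            f"without_threshold={int(frame['without_threshold'].sum())} "
            f"all_data={int(frame['all_data'].sum())}"
        )
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
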