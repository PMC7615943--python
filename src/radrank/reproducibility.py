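"""Rank-order reproducibility of features across extraction arms.

For every feature, the cohort's cases are ranked by their feature value
(average ranks for ties) and two arms are compared by the Spearman rank
correlation rs — the Pearson correlation of the two average-rank
vectors.  A feature is *reproducible* at a cutoff when all required arm
comparisons (scan 1 and scan 2, both aggregation dialects, for a given
threshold state) reach rs ≥ cutoff; the inclusive rule means a value
exactly at the cutoff counts.  Two cutoffs (0.75 and 0.8) are carried
as first-class configuration because both are in common use.

Undefined rs (a constant feature vector, or fewer than two valid paired
cases after NaN exclusion) counts as NOT reproducible and is reported
distinctly from a low rs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    IncompleteDesignError,
    InsufficientDataError,
    PairingError,
    RegistryError,
)
from .features import FEATURE_NAMES, FeatureTable
from .texture import AVERAGED, MERGED


def rank_cases(table: FeatureTable, feature: str) -> pd.Series:
    """Average ranks (1 = smallest) of the cohort for one feature.

    NaN cases are excluded before ranking; fewer than two valid cases
    raise :class:`InsufficientDataError`.
    """
    if feature not in table.frame.columns:
        raise KeyError(f"unknown feature {feature!r}")
    values = table.frame[feature].dropna()
    if len(values) < 2:
        raise InsufficientDataError(
            f"feature {feature!r}: {len(values)} valid cases, need >= 2"
        )
    return pd.Series(
        stats.rankdata(values.to_numpy(), method="average"), index=values.index
    )


def spearman(x, y) -> float:
    """Spearman rs: Pearson correlation of the two average-rank vectors.

    Returns NaN (flagged undefined) when either rank vector is constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise PairingError(f"rank vectors differ in length: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise InsufficientDataError("need >= 2 paired cases for rs")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


@dataclass(frozen=True)
class ArmComparison:
    """rs between two arms for one feature, with pairwise NaN exclusion."""

    feature: str
    arm_a: str
    arm_b: str
    rs: float
    n_pairs: int

    @property
    def valid(self) -> bool:
        return self.n_pairs >= 2 and np.isfinite(self.rs)


def compare_arms(
    table_a: FeatureTable,
    table_b: FeatureTable,
    features: Optional[Iterable[str]] = None,
) -> list[ArmComparison]:
    """One :class:`ArmComparison` per feature between two single-scan tables.

    Tables are paired on case_id; cases with NaN in either arm are
    excluded pairwise for that feature (and n_pairs records how many
    remain).
    """
    fa, fb = table_a.frame, table_b.frame
    if isinstance(fa.index, pd.MultiIndex) or isinstance(fb.index, pd.MultiIndex):
        raise PairingError(
            "compare_arms expects single-scan tables; use select_scan() first"
        )
    common = fa.index.intersection(fb.index)
    if len(common) == 0:
        raise PairingError(
            f"arms {table_a.arm_id!r} and {table_b.arm_id!r} share no cases"
        )
    names = list(features) if features is not None else list(FEATURE_NAMES)
    out = []
    for name in names:
        a = fa.loc[common, name].to_numpy(dtype=np.float64)
        b = fb.loc[common, name].to_numpy(dtype=np.float64)
        ok = np.isfinite(a) & np.isfinite(b)
        n = int(ok.sum())
        rs = spearman(a[ok], b[ok]) if n >= 2 else float("nan")
        out.append(
            ArmComparison(
                feature=name,
                arm_a=table_a.arm_id,
                arm_b=table_b.arm_id,
                rs=rs,
                n_pairs=n,
            )
        )
    return out


class ComparisonKey(NamedTuple):
    """Identifies one required arm comparison in the classification design."""

    thresholded: bool
    scan_id: str
    dialect: str

    @property
    def label(self) -> str:
        t = "threshold" if self.thresholded else "no_threshold"
        return f"{t}/{self.scan_id}/{self.dialect}"


def required_keys(scan_ids: Iterable[str]) -> list[ComparisonKey]:
    return [
        ComparisonKey(t, s, d)
        for t in (True, False)
        for s in scan_ids
        for d in (MERGED, AVERAGED)
    ]


@dataclass
class ReproducibilityReport:
    """Per-feature rs values for every design comparison plus tick columns.

    ``ticks[cutoff]`` is a boolean frame with columns ``with_threshold``
    (all four thresholded comparisons at rs ≥ cutoff), ``without_threshold``
    (analogous), and ``all_data`` (both).
    """

    rs: pd.DataFrame  # features × comparison labels
    ticks: dict[float, pd.DataFrame] = field(default_factory=dict)
    cutoffs: tuple[float, ...] = (0.75, 0.8)
    n_pairs: Optional[pd.DataFrame] = None

    def ticked(self, cutoff: float, column: str = "all_data") -> set[str]:
        return set(self.ticks[cutoff].index[self.ticks[cutoff][column]])

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "cutoffs": list(self.cutoffs),
            "rs": {
                feat: {col: _jsonable(v) for col, v in row.items()}
                for feat, row in self.rs.iterrows()
            },
            "ticks": {
                str(c): {
                    feat: {col: bool(v) for col, v in row.items()}
                    for feat, row in frame.iterrows()
                }
                for c, frame in self.ticks.items()
            },
        }
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(payload, indent=1))
        return p

    def to_csv(self, path: str | Path) -> Path:
        """rs matrix plus tick columns, mirroring the per-feature table layout."""
        frame = self.rs.copy()
        for c in self.cutoffs:
            for col in ("with_threshold", "without_threshold", "all_data"):
                frame[f"{col}@{c:g}"] = self.ticks[c][col]
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(p, float_format="%.17g")
        return p


def _jsonable(v):
    v = float(v)
    return v if np.isfinite(v) else None


def classify(
    comparisons: dict[ComparisonKey, list[ArmComparison]],
    cutoffs: Iterable[float] = (0.75, 0.8),
) -> ReproducibilityReport:
    """Build the reproducibility report from the full comparison design.

    Requires every combination of threshold state × scan × dialect to be
    present (for the scan ids appearing in the keys); a missing
    combination raises :class:`IncompleteDesignError`. A tick demands a
    *valid* rs ≥ cutoff in every required comparison — undefined rs
    never counts as reproducible.
    """
    scan_ids = sorted({k.scan_id for k in comparisons})
    if len(scan_ids) < 2:
        raise IncompleteDesignError(
            f"classification needs comparisons from two scans, got {scan_ids}"
        )
    missing = [k.label for k in required_keys(scan_ids) if k not in comparisons]
    if missing:
        raise IncompleteDesignError(f"missing arm comparisons: {missing}")

    keys = required_keys(scan_ids)
    rs = pd.DataFrame(
        index=list(FEATURE_NAMES), columns=[k.label for k in keys], dtype=float
    )
    n_pairs = pd.DataFrame(
        0, index=list(FEATURE_NAMES), columns=[k.label for k in keys], dtype=int
    )
    for key in keys:
        for comp in comparisons[key]:
            rs.loc[comp.feature, key.label] = comp.rs
            n_pairs.loc[comp.feature, key.label] = comp.n_pairs

    cutoffs = tuple(sorted(set(float(c) for c in cutoffs)))
    thr_cols = [k.label for k in keys if k.thresholded]
    no_thr_cols = [k.label for k in keys if not k.thresholded]
    ticks: dict[float, pd.DataFrame] = {}
    for c in cutoffs:
        with_thr = (rs[thr_cols] >= c).all(axis=1) & rs[thr_cols].notna().all(axis=1)
        without_thr = (rs[no_thr_cols] >= c).all(axis=1) & rs[no_thr_cols].notna().all(
            axis=1
        )
        ticks[c] = pd.DataFrame(
            {
                "with_threshold": with_thr,
                "without_threshold": without_thr,
                "all_data": with_thr & without_thr,
            }
        )
    return ReproducibilityReport(rs=rs, ticks=ticks, cutoffs=cutoffs, n_pairs=n_pairs)


@dataclass(frozen=True)
class VennPartition:
    """Set-algebra partition of two ticked-feature sets."""

    only_a: frozenset[str]
    only_b: frozenset[str]
    both: frozenset[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.only_b), len(self.both))


def feature_set_overlap(
    report_a: "ReproducibilityReport | set[str]",
    report_b: "ReproducibilityReport | set[str]",
    cutoff: Optional[float] = None,
    column: str = "all_data",
) -> VennPartition:
    """Overlap of two reports' ticked feature sets (or two raw name sets)."""
    if isinstance(report_a, ReproducibilityReport) and isinstance(
        report_b, ReproducibilityReport
    ):
        if list(report_a.rs.index) != list(report_b.rs.index):
            raise RegistryError("reports use different feature registries")
        if cutoff is None:
            cutoff = report_a.cutoffs[0]
        a = report_a.ticked(cutoff, column)
        b = report_b.ticked(cutoff, column)
    else:
        a = set(report_a)  # type: ignore[arg-type]
        b = set(report_b)  # type: ignore[arg-type]
        unknown = (a | b) - set(FEATURE_NAMES)
        if unknown:
            raise RegistryError(f"names outside the feature registry: {sorted(unknown)}")
    return VennPartition(
        only_a=frozenset(a - b), only_b=frozenset(b - a), both=frozenset(a & b)
    )


def ticked_features(comparisons: list[ArmComparison], cutoff: float) -> set[str]:
    """Features whose single comparison has a valid rs ≥ cutoff.

    Convenience for single-scan cohorts, where the full two-scan
    classification design does not apply.
    """
    return {c.feature for c in comparisons if c.valid and c.rs >= cutoff}
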