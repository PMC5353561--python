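"""Time-course analysis of adaptive-evolution expression data.

Each evolved strain is profiled at a series of time points (in the
emulated design: 384, 744, 1224, 1824 and 2496 hours) against a single
parent strain.  Per gene and strain, the series of log2 fold changes
versus the parent is classified as monotone up, monotone down or
non-monotone, with a stricter "step-wise" flag for series that climb (or
fall) at essentially every step.  Concordance compares these trends with
experimentally annotated tolerance directions: a gene whose
overexpression confers tolerance is expected to drift up during
adaptation, a knockout-tolerance gene down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    DEGTable,
    DIRECTION_KNOCKOUT,
    DIRECTION_OVEREXPRESSION,
    ExpressionStudy,
    GeneSetCollection,
    ValidationError,
)

TREND_UP = "monotone_up"
TREND_DOWN = "monotone_down"
TREND_NONE = "non_monotone"
TREND_NOT_EXPRESSED = "not_expressed"


def classify_monotone(series: Sequence[float], tie_tolerance: float = 0.0) -> str:
    """Classify an ordered series as monotone up/down or non-monotone.

    Monotone up: every consecutive difference >= -tie_tolerance and at
    least one difference > tie_tolerance (a constant series is therefore
    non-monotone).  Monotone down is symmetric.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValidationError("series must have at least 2 points")
    if not np.isfinite(x).all():
        raise ValidationError("series contains non-finite values")
    if tie_tolerance < 0:
        raise ValidationError("tie_tolerance must be >= 0")
    d = np.diff(x)
    if (d >= -tie_tolerance).all() and (d > tie_tolerance).any():
        return TREND_UP
    if (d <= tie_tolerance).all() and (d < -tie_tolerance).any():
        return TREND_DOWN
    return TREND_NONE


def is_stepwise(series: Sequence[float], tie_tolerance: float = 0.0) -> bool:
    """Stricter flag: monotone with strict steps at all but at most one
    consecutive difference (>= 3 strict steps out of 4 in the 5-point
    design)."""
    trend = classify_monotone(series, tie_tolerance)
    if trend == TREND_NONE:
        return False
    d = np.diff(np.asarray(series, dtype=float))
    strict = (d > tie_tolerance) if trend == TREND_UP else (d < -tie_tolerance)
    return int(strict.sum()) >= max(1, len(d) - 1)


def build_trend_table(
    study: ExpressionStudy,
    parent_sample: str,
    detection_threshold: float = 4.0,
    tie_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Per-gene, per-strain trend classification over post-zero time points.

    Returns a long table with columns ``gene``, ``strain``, one
    ``lfc_h{t}`` column per time point (log2 FC versus the parent), and
    ``trend`` / ``stepwise``.  Genes whose mean log2 level across all
    samples is below the detection threshold are classified
    ``not_expressed``.
    """
    if parent_sample not in study.samples:
        raise ValidationError(f"parent sample {parent_sample!r} not in study")
    meta = study.metadata
    evolved = meta[(meta["condition"] == "evolved") & (meta["time_h"].fillna(0) > 0)]
    if evolved.empty:
        raise ValidationError("study contains no evolved samples with time_h > 0")
    timepoints = sorted(int(t) for t in evolved["time_h"].unique())
    expressed = study.values.mean(axis=1) >= detection_threshold
    parent = study.values[parent_sample].to_numpy(dtype=float)

    rows = []
    for strain in sorted(evolved["strain"].unique()):
        samples = []
        for t in timepoints:
            sel = evolved[(evolved["strain"] == strain) & (evolved["time_h"] == t)]
            if len(sel) != 1:
                raise ValidationError(
                    f"strain {strain!r} needs exactly one sample at h{t}, "
                    f"found {len(sel)}"
                )
            samples.append(sel.index[0])
        lfc = study.values.loc[:, samples].to_numpy(dtype=float) - parent[:, None]
        for i, gene in enumerate(study.genes):
            if not expressed[gene]:
                trend, step = TREND_NOT_EXPRESSED, False
            else:
                trend = classify_monotone(lfc[i], tie_tolerance)
                step = is_stepwise(lfc[i], tie_tolerance)
            rows.append((gene, strain, *lfc[i], trend, step))
    cols = ["gene", "strain", *[f"lfc_h{t}" for t in timepoints], "trend", "stepwise"]
    return pd.DataFrame(rows, columns=cols)


def trend_timepoints(trends: pd.DataFrame) -> list[int]:
    return [int(c[len("lfc_h"):]) for c in trends.columns if c.startswith("lfc_h")]


@dataclass
class ConcordanceResult:
    percent: float
    n: int
    per_strain: dict[str, float] = field(default_factory=dict)
    defined: bool = True


def concordance_with_annotation(
    trends: pd.DataFrame,
    sets: GeneSetCollection,
    deg: DEGTable | None = None,
) -> ConcordanceResult:
    """Percent of annotated, differentially expressed genes whose trend
    matches the tolerance annotation.

    overexpression_tolerant genes are expected monotone_up;
    knockout_tolerant genes monotone_down.  When a DEG table is supplied,
    only genes with an up/down call in at least one of its contrasts are
    counted.  Pooled and per-strain tallies are both reported.
    """
    expectation: dict[str, str] = {}
    for s in sets:
        for g, d in s.directions.items():
            if d == DIRECTION_OVEREXPRESSION:
                expectation[g] = TREND_UP
            elif d == DIRECTION_KNOCKOUT:
                expectation[g] = TREND_DOWN
    if deg is not None:
        de_genes = set(deg.genes_called("up")) | set(deg.genes_called("down"))
        expectation = {g: e for g, e in expectation.items() if g in de_genes}

    sub = trends[
        trends["gene"].isin(expectation) & (trends["trend"] != TREND_NOT_EXPRESSED)
    ]
    if sub.empty:
        return ConcordanceResult(percent=float("nan"), n=0, defined=False)
    match = sub.apply(lambda r: r["trend"] == expectation[r["gene"]], axis=1)
    per_strain = {
        strain: 100.0 * m.mean()
        for strain, m in match.groupby(sub["strain"])
    }
    return ConcordanceResult(
        percent=100.0 * match.mean(),
        n=len(sub),
        per_strain=per_strain,
        defined=True,
    )


def region_shift_test(
    study: ExpressionStudy,
    region_genes: Sequence[str],
    timepoint_a: int,
    timepoint_b: int,
    strain: str,
    detection_threshold: float = 4.0,
) -> tuple[float, int]:
    """One-sided Wilcoxon signed-rank test for an upward shift of a gene
    region between two time points of one strain.

    Each expressed region gene contributes a paired observation (its value
    at ``timepoint_a`` and at ``timepoint_b``).  Returns ``(p, n_genes)``;
    p = 1 when all paired differences are zero.
    """
    meta = study.metadata
    samples = {}
    for t in (timepoint_a, timepoint_b):
        sel = meta[(meta["strain"] == strain) & (meta["time_h"] == t)]
        if sel.empty:
            raise ValidationError(f"strain {strain!r} has no sample at h{t}")
        samples[t] = sel.index[0]
    expressed = study.values.mean(axis=1) >= detection_threshold
    genes = [g for g in region_genes if g in study.values.index and expressed[g]]
    if len(genes) < 3:
        raise ValidationError("need at least 3 expressed region genes")
    a = study.values.loc[genes, samples[timepoint_a]].to_numpy(dtype=float)
    b = study.values.loc[genes, samples[timepoint_b]].to_numpy(dtype=float)
    d = b - a
    if np.all(d == 0):
        return 1.0, len(genes)
    p = float(stats.wilcoxon(d, alternative="greater").pvalue)
    return p, len(genes)


def stepwise_pathway_profile(trends: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """Mean log2 FC versus parent at each time point over a gene set,
    pooled across strains — the per-pathway decline/recovery profile."""
    sub = trends[trends["gene"].isin(list(genes)) & (trends["trend"] != TREND_NOT_EXPRESSED)]
    if sub.empty:
        raise ValidationError("gene set has no expressed overlap with trend table")
    cols = [c for c in trends.columns if c.startswith("lfc_h")]
    prof = sub[cols].mean(axis=0)
    prof.index = [int(c[len("lfc_h"):]) for c in cols]
    return prof


def trend_tallies(trends: pd.DataFrame) -> pd.DataFrame:
    """Monotone/step-wise tallies, pooled and per strain."""
    rows = []

    def _tally(label: str, sub: pd.DataFrame) -> None:
        expressed = sub[sub["trend"] != TREND_NOT_EXPRESSED]
        n = len(expressed)
        mono = expressed["trend"].isin([TREND_UP, TREND_DOWN]).sum()
        rows.append(
            {
                "scope": label,
                "n_expressed": n,
                "n_monotone": int(mono),
                "pct_monotone": 100.0 * mono / n if n else np.nan,
                "n_stepwise": int(expressed["stepwise"].sum()),
            }
        )

    _tally("pooled", trends)
    for strain, sub in trends.groupby("strain"):
        _tally(str(strain), sub)
    return pd.DataFrame(rows)
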