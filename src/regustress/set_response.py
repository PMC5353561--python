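"""Gene-set and regulon response profiling.

Given per-contrast differential-expression calls, this module computes the
statistics used to summarize how a regulon or pathway responds to stress:
the proportion of its expressed members called up or down, scalar response
levels suitable for dose-response analysis, correlations of those levels
with a covariate (e.g. ethanol % v/v) or with another process, and a
one-sided hypergeometric over-representation test with optional
Benjamini-Hochberg adjustment across sets.

All proportions are computed over *expressed* set members only; genes
called ``not_expressed`` never enter a denominator.  Displayed percentages
round half away from zero, the convention that reproduces printed values
such as 20/26 -> 77% and 12/13 -> 92%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    CALL_DOWN,
    CALL_NOT_EXPRESSED,
    CALL_UP,
    ContrastDesign,
    DEGTable,
    ExpressionStudy,
    GeneSetCollection,
    ValidationError,
)
from ._utils import pct_display

RESPONSE_METHODS = ("mean_lfc", "prop_up_minus_down", "mean_expression")
CORRELATION_METHODS = ("pearson", "spearman")

PROFILE_COLUMNS = (
    "set",
    "contrast",
    "n_in_set_expressed",
    "n_up",
    "n_down",
    "prop_up",
    "prop_down",
    "pct_up",
    "pct_down",
    "defined",
)


def set_deg_proportions(deg: DEGTable, sets: GeneSetCollection) -> pd.DataFrame:
    """Per-(set, contrast) counts and proportions of up/down members.

    Rows for sets with zero expressed members in a contrast are flagged
    ``defined=False`` and must be excluded from correlations.
    """
    rows = []
    for contrast in deg.contrasts:
        calls = deg.calls(contrast)
        for s in sets:
            member_calls = calls.reindex([g for g in s.genes if g in calls.index])
            expressed = member_calls[member_calls != CALL_NOT_EXPRESSED]
            n_exp = len(expressed)
            n_up = int((expressed == CALL_UP).sum())
            n_down = int((expressed == CALL_DOWN).sum())
            if n_exp == 0:
                rows.append(
                    (s.name, contrast, 0, 0, 0, np.nan, np.nan, np.nan, np.nan, False)
                )
            else:
                pu, pdn = n_up / n_exp, n_down / n_exp
                rows.append(
                    (
                        s.name,
                        contrast,
                        n_exp,
                        n_up,
                        n_down,
                        pu,
                        pdn,
                        pct_display(pu),
                        pct_display(pdn),
                        True,
                    )
                )
    return pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))


def set_response_level(
    study: ExpressionStudy,
    deg: DEGTable,
    genes: Sequence[str],
    method: str,
    contrasts: Sequence[ContrastDesign] | None = None,
) -> pd.Series:
    """A per-contrast scalar response level for one gene set.

    methods
    -------
    ``mean_lfc``
        Mean log2 fold change over expressed set members.
    ``prop_up_minus_down``
        Proportion of expressed members up minus proportion down.
    ``mean_expression``
        Mean log2 level of expressed members over the contrast's treatment
        group (requires ``contrasts``).
    """
    if method not in RESPONSE_METHODS:
        raise ValidationError(f"unknown response-level method {method!r}")
    genes = list(genes)
    if not genes:
        raise ValidationError("empty gene set")
    out = {}
    by_name = {c.name: c for c in contrasts} if contrasts else {}
    for contrast in deg.contrasts:
        sub = deg.for_contrast(contrast)
        sub = sub[sub["gene"].isin(genes) & (sub["call"] != CALL_NOT_EXPRESSED)]
        if sub.empty:
            out[contrast] = np.nan
            continue
        if method == "mean_lfc":
            out[contrast] = float(np.log2(sub["fold_change"]).mean())
        elif method == "prop_up_minus_down":
            out[contrast] = float(
                ((sub["call"] == CALL_UP).mean()) - ((sub["call"] == CALL_DOWN).mean())
            )
        else:
            if contrast not in by_name:
                raise ValidationError(
                    f"mean_expression needs the ContrastDesign for {contrast!r}"
                )
            cd = by_name[contrast]
            out[contrast] = float(
                study.values.loc[list(sub["gene"]), list(cd.treatment)].to_numpy().mean()
            )
    return pd.Series(out, name=method)


def percent_mean_expression_change(
    study: ExpressionStudy,
    parent_sample: str,
    samples: Sequence[str],
    genes: Sequence[str],
) -> float:
    """Percent change of a set's mean linear expression versus the parent.

    E.g. parent mean 100, evolved mean 80 -> -20.0.
    """
    genes = [g for g in genes if g in study.values.index]
    if not genes:
        raise ValidationError("no set member present in study")
    lin = np.power(2.0, study.values.loc[genes])
    parent_mean = float(lin[parent_sample].mean())
    evolved_mean = float(lin[list(samples)].to_numpy().mean())
    return 100.0 * (evolved_mean / parent_mean - 1.0)


@dataclass
class CorrelationResult:
    r: float
    n: int
    method: str
    defined: bool = True


def correlate_with_covariate(
    levels: Sequence[float], covariate: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Correlation of per-contrast response levels with a covariate.

    Pairs containing non-finite values are dropped; at least three finite
    pairs are required.  A constant input vector yields an undefined
    (flagged) result rather than r = 0.
    """
    if method not in CORRELATION_METHODS:
        raise ValidationError(f"unknown correlation method {method!r}")
    x = np.asarray(levels, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("levels and covariate lengths differ")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 finite paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=float("nan"), n=n, method=method, defined=False)
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        r = stats.spearmanr(x, y).statistic
    return CorrelationResult(r=float(r), n=n, method=method, defined=True)


def correlate_processes(
    profile_a: Sequence[float], profile_b: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Correlation between two per-contrast process profiles."""
    return correlate_with_covariate(profile_a, profile_b, method=method)


def enrich_gene_sets(
    deg_genes: Sequence[str],
    universe: Sequence[str],
    sets: GeneSetCollection,
    correction: str = "none",
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per set.

    For each set, p is the probability of drawing at least the observed
    overlap when ``len(deg_genes)`` genes are sampled without replacement
    from the universe.  Sets are intersected with the universe first.
    ``correction='BH'`` adds Benjamini-Hochberg adjusted p-values across
    sets.
    """
    if correction not in ("none", "BH"):
        raise ValidationError(f"unknown correction {correction!r}")
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValidationError("empty universe")
    uni = set(universe)
    deg_genes = list(dict.fromkeys(deg_genes))
    for g in deg_genes:
        if g not in uni:
            raise ValidationError(f"DEG gene {g!r} absent from universe")
    N, n = len(universe), len(deg_genes)
    deg_set = set(deg_genes)
    rows = []
    for s in sets:
        members = [g for g in s.genes if g in uni]
        K = len(members)
        k = len(deg_set.intersection(members))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((s.name, K, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "n_set_in_universe", "n_overlap", "p"])
    if correction == "BH":
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    else:
        out["p_adj"] = np.nan
    return out
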