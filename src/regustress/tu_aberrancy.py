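"""Regulatory-consistency classification of transcription units (TUs).

For transcription factors annotated as ethanol-binding proteins (EBPs), a
TU regulated *solely* by such a TF should follow the TF's
differential-expression state given the edge sign.  A TU that does not is
scored *aberrant* — evidence that ethanol binding has altered the
regulator's function.

The four-case rule (with tf/tu calls in {up, down, ns}):

========== ========= ========= ==============
edge sign  TF call   TU call   verdict
========== ========= ========= ==============
activation ns        down      aberrant
activation up        not up    aberrant
repression ns        up        aberrant
repression up        up        aberrant
========== ========= ========= ==============

All other combinations with TF in {ns, up} are consistent.  The rule never
enumerates a down-regulated TF, so ``tf=down`` combinations are scored
*indeterminate* and excluded from both the numerator and denominator of
per-TF aberrancy percentages rather than silently scored.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CALL_DOWN,
    CALL_NOT_EXPRESSED,
    CALL_NS,
    CALL_UP,
    DEGTable,
    RegulatoryNetwork,
    SIGN_ACTIVATION,
    SIGN_REPRESSION,
    SIGNS,
    ValidationError,
)

VERDICT_ABERRANT = "aberrant"
VERDICT_CONSISTENT = "consistent"
VERDICT_INDETERMINATE = "indeterminate"

TU_RULES = ("majority", "any", "all")


def summarize_member_calls(calls: Sequence[str], rule: str = "majority") -> str:
    """Collapse member-gene calls to a single TU-level call.

    ``majority`` (default): the direction held by more than half of the
    expressed members, else ``ns``.  ``any``: a direction held by at least
    one expressed member provided the opposite direction is absent.
    ``all``: a direction held by every expressed member.  With no expressed
    member the TU is ``not_expressed``.
    """
    if rule not in TU_RULES:
        raise ValidationError(f"unknown TU summarization rule {rule!r}")
    expressed = [c for c in calls if c != CALL_NOT_EXPRESSED]
    if not expressed:
        return CALL_NOT_EXPRESSED
    n = len(expressed)
    n_up = sum(c == CALL_UP for c in expressed)
    n_down = sum(c == CALL_DOWN for c in expressed)
    if rule == "majority":
        if n_up * 2 > n:
            return CALL_UP
        if n_down * 2 > n:
            return CALL_DOWN
        return CALL_NS
    if rule == "any":
        if n_up and not n_down:
            return CALL_UP
        if n_down and not n_up:
            return CALL_DOWN
        return CALL_NS
    # all
    if n_up == n:
        return CALL_UP
    if n_down == n:
        return CALL_DOWN
    return CALL_NS


def summarize_tu(
    deg: DEGTable,
    members: Sequence[str],
    contrast: str,
    rule: str = "majority",
) -> str:
    """TU-level call from the member genes' calls in one contrast."""
    calls = deg.calls(contrast)
    member_calls = [calls[g] for g in members if g in calls.index]
    if not member_calls:
        return CALL_NOT_EXPRESSED
    return summarize_member_calls(member_calls, rule=rule)


def classify_aberrant(tf_call: str, tu_call: str, sign: str) -> str:
    """Verdict for one (TF call, TU call, edge sign) combination."""
    if sign not in SIGNS:
        raise ValidationError(f"unknown regulation sign {sign!r}")
    for name, call in (("TF", tf_call), ("TU", tu_call)):
        if call not in (CALL_UP, CALL_DOWN, CALL_NS):
            raise ValidationError(f"{name} call {call!r} not in {{up, down, ns}}")
    if tf_call == CALL_DOWN:
        return VERDICT_INDETERMINATE
    if sign == SIGN_ACTIVATION:
        if tf_call == CALL_NS and tu_call == CALL_DOWN:
            return VERDICT_ABERRANT
        if tf_call == CALL_UP and tu_call != CALL_UP:
            return VERDICT_ABERRANT
    else:  # repression
        if tf_call == CALL_NS and tu_call == CALL_UP:
            return VERDICT_ABERRANT
        if tf_call == CALL_UP and tu_call == CALL_UP:
            return VERDICT_ABERRANT
    return VERDICT_CONSISTENT


def aberrancy_level(
    network: RegulatoryNetwork,
    deg: DEGTable,
    tf: str,
    contrast: str,
    rule: str = "majority",
) -> dict:
    """Aberrancy summary for one TF in one contrast.

    Only TUs whose sole regulator is ``tf`` are scored.  TUs that are
    indeterminate (TF down, or TU/TF not expressed) are excluded from both
    numerator and denominator; ``percent_aberrant`` is NaN (flagged
    undefined) when the denominator is zero.
    """
    if tf not in network.tfs:
        raise ValidationError(f"TF {tf!r} not present in network")
    calls = deg.calls(contrast)
    tf_call = calls.get(tf, CALL_NOT_EXPRESSED)
    sole = network.sole_regulator_tus(tf)
    verdicts: dict[str, str] = {}
    for edge in sole:
        tu_call = summarize_tu(deg, network.members[edge.tu], contrast, rule=rule)
        if tf_call == CALL_NOT_EXPRESSED or tu_call == CALL_NOT_EXPRESSED:
            verdicts[edge.tu] = VERDICT_INDETERMINATE
        else:
            verdicts[edge.tu] = classify_aberrant(tf_call, tu_call, edge.sign)
    n_scored = sum(v != VERDICT_INDETERMINATE for v in verdicts.values())
    n_aberrant = sum(v == VERDICT_ABERRANT for v in verdicts.values())
    return {
        "tf": tf,
        "contrast": contrast,
        "tf_call": tf_call,
        "n_sole_regulator_tus": len(sole),
        "n_scored": n_scored,
        "n_aberrant": n_aberrant,
        "n_indeterminate": len(sole) - n_scored,
        "percent_aberrant": (100.0 * n_aberrant / n_scored) if n_scored else np.nan,
        "defined": n_scored > 0,
        "verdicts": verdicts,
    }


def aberrancy_report(
    network: RegulatoryNetwork,
    deg: DEGTable,
    tfs: Sequence[str] | None = None,
    contrasts: Sequence[str] | None = None,
    rule: str = "majority",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-TF and per-TU aberrancy tables.

    ``tfs`` defaults to the network's EBP-annotated TFs (falling back to
    all TFs when no EBP annotation is present).
    """
    if tfs is None:
        tfs = sorted(network.ebp_tfs) or network.tfs
    if contrasts is None:
        contrasts = deg.contrasts
    tf_rows, tu_rows = [], []
    for contrast in contrasts:
        for tf in tfs:
            row = aberrancy_level(network, deg, tf, contrast, rule=rule)
            verdicts = row.pop("verdicts")
            tf_rows.append(row)
            for tu, verdict in verdicts.items():
                tu_rows.append(
                    {"tf": tf, "tu": tu, "contrast": contrast, "verdict": verdict}
                )
    return pd.DataFrame(tf_rows), pd.DataFrame(tu_rows)
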