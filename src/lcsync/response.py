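"""Levodopa-responsiveness indices and the response/resistance split.

Responsiveness to a levodopa challenge is summarized by normalized rates of
change between medication OFF and ON states,

    rate = (value_OFF - value_ON) / value_OFF,

applied to the UPDRS-III motor score (positive = improvement) and to
somatomotor-network synchronization (negative when synchrony increases ON,
as in responders).  A cohort is split into a levodopa-response and a
levodopa-resistance group at the median of the ranked UPDRS-III rate; with an
odd cohort the extra subject goes to the response group (57 -> 29/28).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "rate_of_change_updrs",
    "rate_of_change_sync",
    "original_change_updrs",
    "split_by_response",
    "add_response_columns",
]


def _rate(off: float, on: float, what: str) -> float:
    if off <= 0:
        raise ValueError(f"rate of change undefined for {what} OFF <= 0")
    return (off - on) / off


def rate_of_change_updrs(off: float, on: float) -> float:
    """(UPDRS-III_OFF - UPDRS-III_ON) / UPDRS-III_OFF; positive = improvement."""
    return _rate(off, on, "UPDRS-III")


def rate_of_change_sync(off: float, on: float) -> float:
    """(Sync_OFF - Sync_ON) / Sync_OFF; negative when synchrony rises ON."""
    return _rate(off, on, "synchronization")


def original_change_updrs(off: float, on: float) -> float:
    """Unnormalized score change UPDRS-III_OFF - UPDRS-III_ON."""
    return off - on


def add_response_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append rate_updrs and rate_sync columns computed from OFF/ON pairs."""
    out = cohort.copy()
    if (out["updrs3_off"] <= 0).any() or (out["sync_off"] <= 0).any():
        raise ValueError("rates undefined: non-positive OFF values present")
    out["rate_updrs"] = (out["updrs3_off"] - out["updrs3_on"]) / out["updrs3_off"]
    out["rate_sync"] = (out["sync_off"] - out["sync_on"]) / out["sync_off"]
    return out


def split_by_response(cohort: pd.DataFrame, rate_column: str = "rate_updrs") -> pd.DataFrame:
    """Label each subject 'response' or 'resistance' by ranked rate of change.

    Subjects are ranked by ``rate_column`` descending (stable sort, so ties
    keep input order); the top ceil(n/2) are labeled ``response`` and the
    rest ``resistance``.  Rates are not clipped: a worsening subject has a
    negative rate and sorts into resistance naturally.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects to split")
    out = cohort.copy()
    order = np.argsort(-out[rate_column].to_numpy(), kind="stable")
    n_response = int(np.ceil(len(out) / 2))
    labels = np.empty(len(out), dtype=object)
    labels[order[:n_response]] = "response"
    labels[order[n_response:]] = "resistance"
    out["group"] = labels
    return out
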