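"""Classification of phage-induced growth inhibition from kinetic curves.

A phage/strain pair is scored by the endpoint OD difference between the
untreated positive control and the phage-treated wells (replicate means at
the final shared timepoint):

* diff > 0.1           -> strong inhibition
* 0.05 <= diff <= 0.1  -> weak inhibition
* diff < 0.05          -> no influence

The boundaries are closed on the weak interval ("between 0.1 and 0.05") and
strong requires strictly more than 0.1, so every difference maps to exactly
one label.
"""
from __future__ import annotations

import warnings
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import (
    INHIBITION_RANK,
    InhibitionCall,
    InhibitionLabel,
    KineticCurve,
)

DEFAULT_THRESHOLDS: Tuple[float, float] = (0.05, 0.1)


class ContaminationWarning(UserWarning):
    """Negative control grew beyond the allowed endpoint OD."""


def label_from_diff(
    diff: float, thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS
) -> InhibitionLabel:
    """Map an endpoint OD difference to strong/weak/none."""
    weak_lo, strong_lo = thresholds
    if weak_lo > strong_lo:
        raise ValueError("thresholds must be ordered (weak, strong)")
    if diff > strong_lo:
        return InhibitionLabel.STRONG
    if diff >= weak_lo:
        return InhibitionLabel.WEAK
    return InhibitionLabel.NONE


def _as_curves(curves: Union[KineticCurve, Iterable[KineticCurve]]):
    if isinstance(curves, KineticCurve):
        return [curves]
    out = list(curves)
    if not out:
        raise ValueError("at least one replicate curve required")
    return out


def classify_inhibition(
    control: Union[KineticCurve, Iterable[KineticCurve]],
    treated: Union[KineticCurve, Iterable[KineticCurve]],
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
    negative_control: Union[KineticCurve, Iterable[KineticCurve], None] = None,
    contamination_od: float = 0.2,
) -> InhibitionCall:
    """Classify growth inhibition from control vs treated curve replicates.

    All curves must share one timepoint grid. Duplicate wells are averaged
    before differencing; blanks are not subtracted (control and test wells
    are differenced directly). If ``negative_control`` curves are supplied
    and their mean endpoint exceeds ``contamination_od``, a
    :class:`ContaminationWarning` is emitted.
    """
    ctrl = _as_curves(control)
    test = _as_curves(treated)
    grid = ctrl[0].timepoints
    for c in ctrl + test:
        if c.timepoints.shape != grid.shape or not np.allclose(c.timepoints, grid):
            raise ValueError("control and treated curves share no common time grid")

    if negative_control is not None:
        neg = _as_curves(negative_control)
        neg_end = float(np.mean([c.endpoint for c in neg]))
        if neg_end > contamination_od:
            warnings.warn(
                f"negative control endpoint OD {neg_end:.3f} exceeds "
                f"{contamination_od}: possible contamination",
                ContaminationWarning,
                stacklevel=2,
            )

    diff = float(
        np.mean([c.endpoint for c in ctrl]) - np.mean([c.endpoint for c in test])
    )
    return InhibitionCall(endpoint_diff=diff, label=label_from_diff(diff, thresholds))


CallLike = Union[InhibitionCall, InhibitionLabel, str]


def _label_of(call: CallLike) -> InhibitionLabel:
    if isinstance(call, InhibitionCall):
        return call.label
    return InhibitionLabel(call)


def summarize_panel(
    calls: Mapping[str, Mapping[str, CallLike]],
    overlap_label: str = "overlap",
) -> pd.DataFrame:
    """Panel-level lytic coverage: per-phage strong/weak/none percentages.

    Parameters
    ----------
    calls
        Complete phage -> strain -> call matrix over one declared strain
        collection (every phage must report every strain).
    overlap_label
        Row name for the overlapping-activity row, in which each strain is
        classified by its best call across all phages (strong > weak > none).

    Returns
    -------
    pandas.DataFrame
        One row per phage plus the overlap row; columns ``strong``, ``weak``
        and ``none`` as percentages of the strain collection rounded to one
        decimal.
    """
    if not calls:
        raise ValueError("empty call matrix")
    phages = list(calls)
    strains = sorted(calls[phages[0]])
    if not strains:
        raise ValueError("empty strain collection")
    for p in phages:
        if sorted(calls[p]) != strains:
            raise ValueError(f"phage {p!r} does not cover the full strain collection")

    def fractions(labels: Sequence[InhibitionLabel]) -> Dict[str, float]:
        n = len(labels)
        return {
            key.value: round(100.0 * sum(l is key for l in labels) / n, 1)
            for key in (
                InhibitionLabel.STRONG,
                InhibitionLabel.WEAK,
                InhibitionLabel.NONE,
            )
        }

    rows = {}
    for p in phages:
        rows[p] = fractions([_label_of(calls[p][s]) for s in strains])
    best = [
        max((_label_of(calls[p][s]) for p in phages), key=INHIBITION_RANK.__getitem__)
        for s in strains
    ]
    rows[overlap_label] = fractions(best)
    return pd.DataFrame.from_dict(rows, orient="index")[["strong", "weak", "none"]]
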