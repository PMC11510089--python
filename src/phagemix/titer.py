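"""Phage titer estimation from plaque counts on a dilution series.

The estimator is the weighted-dilution formula used for double-agar overlay
enumeration::

    Mf = sum(c) / (V * d * (N1 + 0.5*N2 + 0.25*N3 + ...))

where ``sum(c)`` sums the plaques on all counted plates, ``V`` is the
inoculated volume per plate (mL), ``d`` is the dilution factor of the
least-dilute counted level, and ``N_k`` is the number of counted plates at
the k-th counted dilution (ordered from least to most dilute), with weights
halving at each successive dilution.

Note the halving weights are unusual for a ten-fold dilution series (the
classical combined estimator would weight successive dilutions by the
dilution step, 0.1); the formula is implemented verbatim as used by the
assay protocol. For a single counted dilution it reduces to the classical
``c / (V * d * N)``.
"""
from __future__ import annotations

from typing import Tuple

from .types import PlaqueCountSeries, TiterEstimate

#: plates with fewer/more plaques than this window are excluded as uncountable
DEFAULT_COUNTABLE_RANGE: Tuple[int, int] = (3, 300)


class NoCountablePlatesError(ValueError):
    """Raised when no plate in the series falls in the countable window."""


def estimate_titer(
    series: PlaqueCountSeries,
    countable_range: Tuple[int, int] = DEFAULT_COUNTABLE_RANGE,
) -> TiterEstimate:
    """Estimate phage titer (PFU/mL) from a plaque-count dilution series.

    Parameters
    ----------
    series
        Plaque counts per plate at each dilution, plus the plated volume.
    countable_range
        Inclusive (low, high) plaque-count window defining a countable
        plate. Plates outside the window are dropped before the formula is
        applied.

    Returns
    -------
    TiterEstimate
        The estimate ``mf`` together with the audit terms (``sum_c``,
        ``volume_ml``, ``dilution``, ``weighted_plate_count``), satisfying
        ``mf == sum_c / (volume_ml * dilution * weighted_plate_count)``.

    Raises
    ------
    NoCountablePlatesError
        If the series is empty or every plate is outside the countable
        window (e.g. all plates at zero plaques).
    """
    lo, hi = countable_range
    if lo > hi:
        raise ValueError("countable_range low bound exceeds high bound")

    counted = []  # (dilution, [counts within window])
    for dilution, counts in series.records:
        keep = [c for c in counts if lo <= c <= hi]
        if keep:
            counted.append((dilution, keep))
    if not counted:
        raise NoCountablePlatesError(
            "no plate with a countable number of plaques "
            f"(window {lo}-{hi}); cannot estimate titer"
        )

    # least-dilute counted level first (largest dilution factor)
    counted.sort(key=lambda rec: rec[0], reverse=True)
    d = counted[0][0]
    sum_c = sum(c for _, counts in counted for c in counts)
    weighted = sum(len(counts) * 0.5**k for k, (_, counts) in enumerate(counted))
    mf = sum_c / (series.volume_ml * d * weighted)
    return TiterEstimate(
        mf=mf,
        sum_c=sum_c,
        volume_ml=series.volume_ml,
        dilution=d,
        weighted_plate_count=weighted,
    )
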