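"""Strain sensitivity calls from serial-dilution spot tests.

A strain is spotted with a ten-fold dilution ladder of the cocktail; each
spot is read as clearance (CL), turbidity (T), discrete plaques (P) or no
lysis (NL). Per replicate, the lowest spotted titer showing any positive
sign is banded by its order of magnitude:

* band 10^3-10^5 PFU/mL -> sensitive
* band 10^6-10^8 PFU/mL -> intermediate
* no positive spot      -> insensitive

Banding uses floor(log10(titer)) so a ladder printed as 2 x 10^k maps into
the power-of-ten bands. Titers below the 10^3 band (more sensitive than the
stated window) are still called sensitive. Replicate calls are combined by
majority, with ties resolved toward the less sensitive label.
"""
from __future__ import annotations

from collections import Counter
from typing import Dict, Iterable, Mapping, Sequence

from .types import (
    POSITIVE_OBSERVATIONS,
    SENSITIVITY_RANK,
    SensitivityCall,
    SensitivityLabel,
    SpotSeries,
    order_of_magnitude,
)

#: inclusive order-of-magnitude band edges
SENSITIVE_BAND = (3, 5)
INTERMEDIATE_BAND = (6, 8)


def _replicate_call(series: SpotSeries) -> SensitivityCall:
    positives = [t for t, obs in series.spots if obs in POSITIVE_OBSERVATIONS]
    if not positives:
        return SensitivityCall(SensitivityLabel.INSENSITIVE, None)
    lowest = min(positives)
    band = order_of_magnitude(lowest)
    if band <= SENSITIVE_BAND[1]:
        return SensitivityCall(SensitivityLabel.SENSITIVE, lowest)
    return SensitivityCall(SensitivityLabel.INTERMEDIATE, lowest)


def call_sensitivity(replicates: Sequence[SpotSeries]) -> SensitivityCall:
    """Combine replicate spot series into one strain sensitivity call.

    All replicates must share the dilution ladder. The consensus label is
    the majority of per-replicate labels; ties go to the less sensitive
    label. The reported ``lowest_positive_titer`` is the smallest positive
    titer among replicates agreeing with the consensus (``None`` for an
    insensitive call).
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("at least one replicate required")
    ladder = reps[0].ladder
    for r in reps[1:]:
        if r.ladder != ladder:
            raise ValueError("inconsistent dilution ladders across replicates")

    calls = [_replicate_call(r) for r in reps]
    counts = Counter(c.label for c in calls)
    top = max(counts.values())
    # ties resolved toward the less sensitive label (lower rank)
    label = min(
        (lbl for lbl, n in counts.items() if n == top),
        key=SENSITIVITY_RANK.__getitem__,
    )
    lows = [
        c.lowest_positive_titer
        for c in calls
        if c.label is label and c.lowest_positive_titer is not None
    ]
    return SensitivityCall(label, min(lows) if lows else None)


def summarize_host_range(
    calls: Mapping[str, SensitivityCall],
) -> Dict[str, float]:
    """Percentage of strains per sensitivity label, rounded to one decimal."""
    if not calls:
        raise ValueError("no sensitivity calls to summarize")
    n = len(calls)
    labels = [c.label for c in calls.values()]
    return {
        key.value: round(100.0 * sum(l is key for l in labels) / n, 1)
        for key in (
            SensitivityLabel.SENSITIVE,
            SensitivityLabel.INTERMEDIATE,
            SensitivityLabel.INSENSITIVE,
        )
    }


def summarize_host_range_by_species(
    calls: Mapping[str, SensitivityCall],
    species_of: Mapping[str, str],
) -> Dict[str, Dict[str, float]]:
    """Per-species label percentages (one summary per species)."""
    groups: Dict[str, Dict[str, SensitivityCall]] = {}
    for strain, call in calls.items():
        groups.setdefault(species_of[strain], {})[strain] = call
    return {sp: summarize_host_range(g) for sp, g in groups.items()}
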