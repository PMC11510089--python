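"""Biofilm-control effectiveness and milk-model log-reduction statistics.

Effectiveness of biofilm control (EBC) compares MTT-stained biofilm
absorbance (OD570) of treated wells against the untreated 100% biofilm
control::

    EBC = 100 - mean(A_TS) * 100 / mean(A_C100)      [percent]

EBC may be negative (biofilm grew more under treatment) and is not clamped.

Milk-model efficacy is the percent reduction in the log-scale bacterial
burden after 24 h, relative to the buffer control assumed as 100%::

    reduction = 100 * (1 - mean(log10 N_phage) / mean(log10 N_control))

with a two-sided two-sample t-test on the log10 counts (Student pooled
variance by default, Welch optional) and significance stars at
p < 0.05 / 0.01 / 0.001.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import stats

from .types import BiofilmMeasurement, MilkAssayResult


def ebc(measurement: BiofilmMeasurement) -> float:
    """Effectiveness of biofilm control, in percent (not clamped)."""
    c100 = float(np.mean(measurement.a_c100))
    if c100 <= 0:
        raise ValueError("100% biofilm control absorbance must be positive")
    return 100.0 - float(np.mean(measurement.a_ts)) * 100.0 / c100


@dataclass(frozen=True)
class EbcSummary:
    threshold: float
    n_at_or_above: int
    n_total: int
    percent: int  # integer-rounded percentage of strains


def summarize_ebc(ebc_by_strain: Mapping[str, float], threshold: float = 50.0) -> EbcSummary:
    """Fraction of strains whose EBC meets a threshold (integer percent)."""
    if not ebc_by_strain:
        raise ValueError("no EBC values to summarize")
    n = len(ebc_by_strain)
    hits = sum(v >= threshold for v in ebc_by_strain.values())
    return EbcSummary(
        threshold=threshold,
        n_at_or_above=hits,
        n_total=n,
        percent=int(round(100.0 * hits / n)),
    )


def significance_stars(p: Optional[float]) -> str:
    """Breakpoints exactly at 0.05 / 0.01 / 0.001."""
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class LogReduction:
    reduction_percent: float
    p_value: Optional[float]
    stars: str
    single_replicate: bool = False


def log_reduction(
    phage_arm: MilkAssayResult,
    control_arm: MilkAssayResult,
    welch: bool = False,
) -> LogReduction:
    """Percent log-scale reduction of the phage arm vs the buffer control.

    With a single replicate in either arm the reduction is still computed
    but the p-value is withheld (``single_replicate`` flag set). Degenerate
    zero-variance arms get p = 1.0 when the means agree and p = 0.0
    otherwise.
    """
    if phage_arm.arm != "phage" or control_arm.arm != "control":
        raise ValueError("arguments must be the phage and control arms, in order")
    lp = np.log10(np.asarray(phage_arm.endpoint_counts))
    lc = np.log10(np.asarray(control_arm.endpoint_counts))
    if np.mean(lc) == 0:
        raise ValueError("control arm log10 mean is zero; reduction undefined")
    reduction = 100.0 * (1.0 - float(np.mean(lp)) / float(np.mean(lc)))

    if lp.size < 2 or lc.size < 2:
        return LogReduction(reduction, None, "", single_replicate=True)
    if np.ptp(lp) == 0 and np.ptp(lc) == 0:
        p = 1.0 if np.mean(lp) == np.mean(lc) else 0.0
    else:
        _, p = stats.ttest_ind(lp, lc, equal_var=not welch)
        p = float(p)
    return LogReduction(reduction, p, significance_stars(p))


def milk_panel(
    arms: Mapping[Tuple[str, float], Dict[str, MilkAssayResult]],
    welch: bool = False,
) -> Dict[Tuple[str, float], LogReduction]:
    """Log reduction per (strain, initial density) pair of paired arms."""
    out = {}
    for key, pair in arms.items():
        out[key] = log_reduction(pair["phage"], pair["control"], welch=welch)
    return out
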