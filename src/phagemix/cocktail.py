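"""Receptor-diverse cocktail selection, formulation and storage stability.

The design principle: combine phages that recognize *different* conserved
surface receptors, so that a single receptor-loss mutation never escapes
the whole cocktail, and keep at least one "core" phage whose receptor
survives the resistance mechanisms raised against the other components.
Cocktails are designed per host species (anti-E. coli and anti-S. aureus
components independently).

Selection is greedy maximum coverage: at each step add the phage covering
the most not-yet-covered strains, tie-broken by (1) fewest main-receptor
classes shared with the already-selected phages, (2) most strains strongly
inhibited, (3) fewest support-receptor classes shared, (4) lexicographic
phage id; stop when coverage stops improving or the size cap is reached.
Greedy maximum coverage carries the classical (1 - 1/e) approximation
guarantee at any fixed cocktail size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .kinetics import CallLike, _label_of
from .types import (
    CellState,
    CocktailDesign,
    CrossSensitivityMatrix,
    InhibitionLabel,
    PhageRecord,
    StabilitySeries,
)

#: calls that count as covering a strain (configurable to strong-only)
DEFAULT_COVERING = frozenset({InhibitionLabel.STRONG, InhibitionLabel.WEAK})


def _coverage_sets(
    lytic: Mapping[str, Mapping[str, CallLike]],
    covering: FrozenSet[InhibitionLabel],
) -> Tuple[Dict[str, Set[str]], Dict[str, int], Set[str]]:
    covered_by: Dict[str, Set[str]] = {}
    strong_count: Dict[str, int] = {}
    strains: Set[str] = set()
    for phage, row in lytic.items():
        labels = {s: _label_of(c) for s, c in row.items()}
        covered_by[phage] = {s for s, l in labels.items() if l in covering}
        strong_count[phage] = sum(l is InhibitionLabel.STRONG for l in labels.values())
        strains.update(labels)
    return covered_by, strong_count, strains


def design_cocktail(
    lytic: Mapping[str, Mapping[str, CallLike]],
    phages: Sequence[PhageRecord],
    cross: Optional[CrossSensitivityMatrix] = None,
    max_size: Optional[int] = None,
    covering: Iterable[InhibitionLabel] = DEFAULT_COVERING,
) -> CocktailDesign:
    """Select a coverage-maximizing, receptor-diverse phage cocktail.

    Parameters
    ----------
    lytic
        phage -> strain -> inhibition call matrix for one host species.
    phages
        Receptor-annotated records for (at least) every phage in ``lytic``.
    cross
        Optional resistant-variant cross-sensitivity matrix; when given it
        drives the resilience and core-phage evaluation, otherwise
        receptor-class distinctness stands in.
    max_size
        Optional cap on cocktail size.
    covering
        Inhibition labels that count as covering a strain.

    Returns
    -------
    CocktailDesign
        Selected phages, coverage fraction, per-strain redundancy depth
        (covering phages counted once per distinct main-receptor class),
        per-strain resilience (still covered after loss of any single
        selected phage) and core phages.
    """
    if not lytic:
        raise ValueError("empty lytic-activity panel")
    records = {p.phage_id: p for p in phages}
    missing = set(lytic) - set(records)
    if missing:
        raise ValueError(f"no PhageRecord for panel phages: {sorted(missing)}")
    species = {records[p].host_species for p in lytic}
    if len(species) > 1:
        raise ValueError(
            f"panel mixes host species {sorted(species)}; design per species"
        )
    covering = frozenset(InhibitionLabel(c) for c in covering)
    covered_by, strong_count, strains = _coverage_sets(lytic, covering)
    if not strains:
        raise ValueError("panel declares no strains")

    selected: List[str] = []
    covered: Set[str] = set()
    cap = max_size if max_size is not None else len(covered_by)
    while len(selected) < cap:
        candidates = [p for p in covered_by if p not in selected]
        if not candidates:
            break
        selected_mains: Set[str] = set().union(
            *(records[p].main_receptors for p in selected), set()
        )
        selected_supports: Set[str] = set().union(
            *(records[p].support_receptors for p in selected), set()
        )

        def key(p: str):
            gain = len(covered_by[p] - covered)
            shared_main = len(records[p].main_receptors & selected_mains)
            shared_support = len(records[p].support_receptors & selected_supports)
            return (-gain, shared_main, -strong_count[p], shared_support, p)

        best = min(candidates, key=key)
        if not covered_by[best] - covered:
            break  # coverage stopped improving
        selected.append(best)
        covered |= covered_by[best]

    redundancy = {
        s: _redundancy_depth(s, selected, covered_by, records) for s in covered
    }
    resilience = {
        s: _is_resilient(s, selected, covered_by, records, cross) for s in covered
    }
    core = _core_phages(selected, cross) if cross is not None else ()
    return CocktailDesign(
        selected=tuple(selected),
        coverage=len(covered) / len(strains),
        covered_strains=frozenset(covered),
        redundancy_depth=redundancy,
        resilience=resilience,
        core_phages=core,
    )


def _redundancy_depth(strain, selected, covered_by, records) -> int:
    """Covering phages counted once per distinct main-receptor class set."""
    covering = [p for p in selected if strain in covered_by[p]]
    classes = {records[p].main_receptors for p in covering}
    # phages without receptor annotation each count individually
    unannotated = sum(1 for p in covering if not records[p].main_receptors)
    annotated = len({c for c in classes if c})
    return annotated + unannotated


def _is_resilient(strain, selected, covered_by, records, cross) -> bool:
    """Covered after the loss of any single covering phage?

    With a cross matrix: for each covering phage p that raised resistant
    variants, some other selected phage must stay sensitive across all of
    p's variants (and still cover the strain). Without one, receptor-class
    distinctness stands in: at least two covering phages with distinct
    main-receptor classes.
    """
    covering = [p for p in selected if strain in covered_by[p]]
    if len(covering) < 2:
        return False
    if cross is None:
        return _redundancy_depth(strain, selected, covered_by, records) >= 2
    for p in covering:
        rows = [v for v in cross.variants if v.inducing_phage_id == p]
        others = [q for q in covering if q != p]
        if not rows:
            if not others:
                return False
            continue
        ok = any(
            all(
                cross.cell(v.variant_id, q) is CellState.SENSITIVE
                for v in rows
                if cross.cell(v.variant_id, q) is not CellState.NOT_TESTED
            )
            and any(
                cross.cell(v.variant_id, q) is not CellState.NOT_TESTED for v in rows
            )
            for q in others
        )
        if not ok:
            return False
    return True


def _core_phages(selected, cross: CrossSensitivityMatrix) -> Tuple[str, ...]:
    """Selected phages sensitive across all resistant variants of the others."""
    core = []
    for p in selected:
        rows = [
            v
            for v in cross.variants
            if v.inducing_phage_id != p and v.inducing_phage_id in selected
        ]
        tested = [
            v for v in rows if cross.cell(v.variant_id, p) is not CellState.NOT_TESTED
        ]
        if tested and all(
            cross.cell(v.variant_id, p) is CellState.SENSITIVE for v in tested
        ):
            core.append(p)
    return tuple(core)


def brute_force_coverage(
    lytic: Mapping[str, Mapping[str, CallLike]],
    max_size: Optional[int] = None,
    covering: Iterable[InhibitionLabel] = DEFAULT_COVERING,
) -> Tuple[float, Tuple[str, ...]]:
    """Exhaustive-subset maximum coverage (oracle for small panels).

    Returns the best coverage fraction and the lexicographically smallest
    subset achieving it. Exponential in panel size; intended for <= ~15
    phages.
    """
    covering = frozenset(InhibitionLabel(c) for c in covering)
    covered_by, _, strains = _coverage_sets(lytic, covering)
    phage_ids = sorted(covered_by)
    cap = max_size if max_size is not None else len(phage_ids)
    best_cov, best_subset = -1.0, ()
    for k in range(0, cap + 1):
        for subset in combinations(phage_ids, k):
            cov = len(set().union(*(covered_by[p] for p in subset), set())) / len(
                strains
            )
            if cov > best_cov:
                best_cov, best_subset = cov, subset
    return best_cov, best_subset


# ---------------------------------------------------------------------------
# formulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Formulation:
    """Equal-split per-phage titer within a cocktail component."""

    n_phages: int
    component_titer: float
    per_phage_titer: float  # exact value, component_titer / n
    per_phage_titer_reported: float  # rounded to one significant digit


def round_1sig(x: float) -> float:
    """Round to one significant digit (2e7 stays 2e7; 3.33e7 -> 3e7)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x / 10**exp) * 10.0**exp


def formulate(selected: Sequence[str] | int, component_titer: float) -> Formulation:
    """Split a component titer equally across the selected phages.

    ``selected`` may be the list of phage ids or simply their count.
    """
    n = selected if isinstance(selected, int) else len(list(selected))
    if n < 1:
        raise ValueError("at least one phage required")
    if component_titer <= 0:
        raise ValueError("component titer must be positive")
    exact = component_titer / n
    return Formulation(
        n_phages=n,
        component_titer=component_titer,
        per_phage_titer=exact,
        per_phage_titer_reported=round_1sig(exact),
    )


# ---------------------------------------------------------------------------
# storage stability
# ---------------------------------------------------------------------------

def stability_percent(series: StabilitySeries) -> pd.DataFrame:
    """Storage stability as %Log of the summed cocktail titer.

    stability(t) = 100 * log10(final_titer(t)) / log10(final_titer(0)),
    where final_titer sums the component titers. The reported column is
    rounded to the nearest integer; the raw value is retained.

    Returns a DataFrame with columns ``month``, ``final_titer``,
    ``stability_raw`` and ``stability``.
    """
    finals = series.final_titers()
    ref = finals[0]
    if ref <= 1.0:
        raise ValueError("reference titer must exceed 1 PFU/mL")
    rows = []
    for month, final in zip(series.months, finals):
        if final <= 1.0:
            raise ValueError(f"titer at month {month} must exceed 1 PFU/mL")
        raw = 100.0 * math.log10(final) / math.log10(ref)
        rows.append(
            {
                "month": month,
                "final_titer": final,
                "stability_raw": raw,
                "stability": int(round(raw)),
            }
        )
    return pd.DataFrame(rows)
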