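"""Resistant-variant cross-sensitivity analysis and receptor confirmation.

Variants raised against one phage are spot-tested against the remaining
cocktail candidates. This module summarizes how many other phages still
lyse each variant (the cross-sensitivity distribution), which phages rescue
the most variants, and which are *core* phages — sensitive in every variant
row where they were tested, i.e. phages whose receptor survives every
observed resistance mechanism.

Receptor-prediction confirmation maps the genes mutated in sequenced
variants onto receptor classes: a genome-based receptor prediction for a
phage is confirmed when, for some variant resistant to it, every mutated
non-silent gene maps into the predicted receptor set; partially confirmed
when only a subset maps; not confirmed when sequenced resistant variants
exist but nothing maps; and no-data when no resistant variant of that phage
was sequenced. Intergenic records (e.g. partial 5S rRNA calls) cannot
affect phage-receptor interaction and are excluded throughout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .types import (
    SILENT_EFFECTS,
    CellState,
    ConfirmationStatus,
    CrossSensitivityMatrix,
    MutationRecord,
    ReceptorConfirmation,
)

#: curated default gene -> receptor-class map (editable; shipped as a
#: packaged CSV as well, see :func:`phagemix.io.load_fixture`)
DEFAULT_GENE_RECEPTOR_MAP: Mapping[str, str] = {
    "ompC": "OmpC",
    "ompA": "OmpA",
    "wzzB": "LPS-O-antigen",
    "wbbD": "LPS-O-antigen",
    "tarS": "WTA-beta-GlcNAc",
}


class UnmappedGeneWarning(UserWarning):
    """A mutated gene is absent from the gene -> receptor map."""


@dataclass(frozen=True)
class CrossSummary:
    """Headline numbers of a cross-sensitivity matrix."""

    sensitive_counts: Mapping[str, int]  # variant -> phages it stays sensitive to
    distribution: Mapping[str, int]  # {">=2", "==1", "==0"} -> variant count
    rescue_counts: Mapping[str, int]  # phage -> variants it still lyses
    core_phages: Tuple[str, ...]
    n_variants: int


def analyze_cross_sensitivity(matrix: CrossSensitivityMatrix) -> CrossSummary:
    """Summarize a variant x phage cross-sensitivity matrix.

    Not-tested cells are excluded from all denominators. A phage is *core*
    when it is sensitive in every variant row where it was tested (and was
    tested at least once); its rescue count then equals its tested rows.
    """
    sensitive_counts: Dict[str, int] = {}
    for v in matrix.variants:
        sensitive_counts[v.variant_id] = sum(
            matrix.cell(v.variant_id, p) is CellState.SENSITIVE for p in matrix.phages
        )
    dist = {
        ">=2": sum(n >= 2 for n in sensitive_counts.values()),
        "==1": sum(n == 1 for n in sensitive_counts.values()),
        "==0": sum(n == 0 for n in sensitive_counts.values()),
    }
    rescue: Dict[str, int] = {}
    core: List[str] = []
    for p in matrix.phages:
        states = [matrix.cell(v.variant_id, p) for v in matrix.variants]
        tested = [s for s in states if s is not CellState.NOT_TESTED]
        rescue[p] = sum(s is CellState.SENSITIVE for s in tested)
        if tested and all(s is CellState.SENSITIVE for s in tested):
            core.append(p)
    return CrossSummary(
        sensitive_counts=sensitive_counts,
        distribution=dist,
        rescue_counts=rescue,
        core_phages=tuple(core),
        n_variants=len(matrix),
    )


def resistant_variants_of(
    matrix: CrossSensitivityMatrix, phage_id: str
) -> Tuple[str, ...]:
    """Variant ids whose tested cell for ``phage_id`` is insensitive."""
    return tuple(
        v.variant_id
        for v in matrix.variants
        if matrix.cell(v.variant_id, phage_id) is CellState.INSENSITIVE
    )


def confirm_receptors(
    predictions: Mapping[str, Iterable[str]],
    mutations: Sequence[MutationRecord],
    matrix: CrossSensitivityMatrix,
    gene_map: Mapping[str, str] = DEFAULT_GENE_RECEPTOR_MAP,
) -> List[ReceptorConfirmation]:
    """Confirm genome-based receptor predictions against resistant mutants.

    Parameters
    ----------
    predictions
        phage id -> predicted receptor-class labels (from genome analysis).
    mutations
        Gene-level mutation calls for the sequenced resistant variants.
        Silent/intergenic records are ignored.
    matrix
        Cross-sensitivity matrix defining which variants are resistant to
        which phage.
    gene_map
        gene symbol -> receptor class. A mutated gene absent from the map
        triggers an :class:`UnmappedGeneWarning` and counts as non-matching.

    Returns
    -------
    list of ReceptorConfirmation, one per phage in ``predictions``.
    """
    genes_by_variant: Dict[str, Set[str]] = {}
    for m in mutations:
        if m.effect in SILENT_EFFECTS:
            continue
        genes_by_variant.setdefault(m.variant_id, set()).add(m.gene)

    out: List[ReceptorConfirmation] = []
    for phage_id, pred in predictions.items():
        predicted = frozenset(pred)
        resistant = resistant_variants_of(matrix, phage_id)
        sequenced = [v for v in resistant if genes_by_variant.get(v)]
        if not sequenced:
            out.append(
                ReceptorConfirmation(
                    phage_id, predicted, (), ConfirmationStatus.NO_DATA
                )
            )
            continue
        full: List[str] = []
        partial: List[str] = []
        for vid in sequenced:
            mapped = set()
            n_mappable = 0
            for gene in sorted(genes_by_variant[vid]):
                cls = gene_map.get(gene)
                if cls is None:
                    warnings.warn(
                        f"gene {gene!r} (variant {vid}) absent from the "
                        "gene->receptor map; treated as non-matching",
                        UnmappedGeneWarning,
                        stacklevel=2,
                    )
                    continue
                n_mappable += 1
                if cls in predicted:
                    mapped.add(gene)
            total = len(genes_by_variant[vid])
            if mapped and len(mapped) == total:
                full.append(vid)
            elif mapped:
                partial.append(vid)
        if full:
            status = ConfirmationStatus.CONFIRMED
            supporting = tuple(full + partial)
        elif partial:
            status = ConfirmationStatus.PARTIALLY_CONFIRMED
            supporting = tuple(partial)
        else:
            status = ConfirmationStatus.NOT_CONFIRMED
            supporting = ()
        out.append(ReceptorConfirmation(phage_id, predicted, supporting, status))
    return out
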