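"""Core domain types shared across the assay-analysis modules.

The types model the artefacts of a phage-cocktail development campaign:
plaque-count dilution series, plate-reader kinetic curves, spot-test
ladders, resistant-variant cross-sensitivity grids, receptor annotations,
cocktail designs and storage-stability series.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# enums
# ---------------------------------------------------------------------------

class Phenotype(str, Enum):
    """Growth response of a strain challenged with phage (kinetic assay)."""

    FULL_INHIBITION = "full_inhibition"
    PARTIAL_INHIBITION = "partial_inhibition"
    TRANSIENT_INHIBITION = "transient_inhibition"
    NO_EFFECT = "no_effect"


class InhibitionLabel(str, Enum):
    """Endpoint-difference classification of a kinetic curve pair."""

    STRONG = "strong"
    WEAK = "weak"
    NONE = "none"


#: ranking used when aggregating calls across phages (best call wins)
INHIBITION_RANK: Mapping[InhibitionLabel, int] = {
    InhibitionLabel.STRONG: 2,
    InhibitionLabel.WEAK: 1,
    InhibitionLabel.NONE: 0,
}


class WellRole(str, Enum):
    TEST = "test"
    POSITIVE_CONTROL = "positive_control"
    NEGATIVE_CONTROL = "negative_control"
    BLANK = "blank"


class SpotObservation(str, Enum):
    """Four-letter spot-test reading: clearance, turbidity, plaques, none."""

    CL = "CL"
    T = "T"
    P = "P"
    NL = "NL"


#: observations counting as evidence of lysis at a spotted dilution
POSITIVE_OBSERVATIONS = frozenset(
    {SpotObservation.CL, SpotObservation.T, SpotObservation.P}
)


class SensitivityLabel(str, Enum):
    SENSITIVE = "sensitive"
    INTERMEDIATE = "intermediate"
    INSENSITIVE = "insensitive"


#: ordering from least to most sensitive, used for conservative tie-breaking
SENSITIVITY_RANK: Mapping[SensitivityLabel, int] = {
    SensitivityLabel.INSENSITIVE: 0,
    SensitivityLabel.INTERMEDIATE: 1,
    SensitivityLabel.SENSITIVE: 2,
}


class CellState(str, Enum):
    """Cross-sensitivity matrix cell: sensitive / insensitive / not tested."""

    SENSITIVE = "+"
    INSENSITIVE = "-"
    NOT_TESTED = "x"


class MutationEffect(str, Enum):
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    MISSENSE = "missense"
    INTERGENIC = "intergenic"


#: effects that cannot disrupt a receptor protein and are ignored in
#: receptor-confirmation logic (e.g. intergenic 5S rRNA calls)
SILENT_EFFECTS = frozenset({MutationEffect.INTERGENIC})


class ConfirmationStatus(str, Enum):
    CONFIRMED = "confirmed"
    PARTIALLY_CONFIRMED = "partially_confirmed"
    NOT_CONFIRMED = "not_confirmed"
    NO_DATA = "no_data"


# ---------------------------------------------------------------------------
# assay records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhageRecord:
    """A phage with host species, taxonomy and receptor-class annotations.

    ``main_receptors`` are the conserved surface structures a phage binds
    irreversibly (porins, LPS core sugars, WTA GlcNAc decorations);
    ``support_receptors`` only assist adsorption and are used solely as a
    late tie-break in cocktail design.
    """

    phage_id: str
    host_species: str
    family: str = ""
    genus: str = ""
    main_receptors: frozenset = frozenset()
    support_receptors: frozenset = frozenset()
    short_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "main_receptors", frozenset(self.main_receptors))
        object.__setattr__(
            self, "support_receptors", frozenset(self.support_receptors)
        )
        if not self.phage_id:
            raise ValueError("phage_id must be non-empty")


@dataclass(frozen=True)
class PlaqueCountSeries:
    """Plaque counts per plate across a dilution series.

    ``records`` maps each dilution factor (in (0, 1], e.g. 1e-6 for the
    sixth ten-fold dilution) to the plaque counts of its replicate plates.
    ``volume_ml`` is the inoculated lysate volume V per plate.
    """

    records: Tuple[Tuple[float, Tuple[int, ...]], ...]
    volume_ml: float = 0.1

    def __post_init__(self) -> None:
        norm = tuple(
            (float(d), tuple(int(c) for c in counts)) for d, counts in self.records
        )
        object.__setattr__(self, "records", norm)
        if self.volume_ml <= 0:
            raise ValueError("inoculum volume must be positive")
        for d, counts in self.records:
            if not (0 < d <= 1):
                raise ValueError(f"dilution factor {d} outside (0, 1]")
            if any(c < 0 for c in counts):
                raise ValueError("plaque counts must be non-negative")
        dils = [d for d, _ in self.records]
        if len(set(dils)) != len(dils):
            raise ValueError("duplicate dilution levels")

    @property
    def dilutions(self) -> Tuple[float, ...]:
        return tuple(d for d, _ in self.records)


@dataclass(frozen=True)
class TiterEstimate:
    """Weighted-dilution titer estimate with its audit terms.

    Mf = sum_c / (V * d * weighted_plate_count) holds exactly.
    """

    mf: float
    sum_c: int
    volume_ml: float
    dilution: float
    weighted_plate_count: float

    def __post_init__(self) -> None:
        if self.mf < 0:
            raise ValueError("titer must be non-negative")


class KineticCurve:
    """A plate-reader OD time series (one well, or a replicate average).

    Parameters
    ----------
    timepoints : strictly increasing times in minutes
    od : absorbance readings (620 nm lytic assay, 600 nm biofilm kinetics)
    role : well role on the plate
    replicate_id : free-form replicate tag
    """

    __slots__ = ("timepoints", "od", "role", "replicate_id")

    def __init__(self, timepoints, od, role=WellRole.TEST, replicate_id="r1"):
        self.timepoints = np.asarray(timepoints, dtype=float)
        self.od = np.asarray(od, dtype=float)
        self.role = WellRole(role)
        self.replicate_id = str(replicate_id)
        if self.timepoints.ndim != 1 or self.timepoints.shape != self.od.shape:
            raise ValueError("timepoints and od must be 1-D and equal length")
        if self.timepoints.size == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od values must be non-negative")

    @property
    def endpoint(self) -> float:
        return float(self.od[-1])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"KineticCurve(n={self.timepoints.size}, role={self.role.value}, "
            f"endpoint={self.endpoint:.3f})"
        )


@dataclass(frozen=True)
class InhibitionCall:
    """Replicate-averaged endpoint OD difference and its label."""

    endpoint_diff: float
    label: InhibitionLabel


@dataclass(frozen=True)
class SpotSeries:
    """One replicate of a serial-dilution spot test on one strain."""

    strain_id: str
    spots: Tuple[Tuple[float, SpotObservation], ...]
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        norm = tuple(
            (float(t), SpotObservation(o)) for t, o in self.spots
        )
        object.__setattr__(self, "spots", norm)
        if not self.spots:
            raise ValueError("empty dilution ladder")
        titers = [t for t, _ in self.spots]
        if any(t <= 0 for t in titers):
            raise ValueError("spotted titers must be positive")
        if not all(a > b for a, b in zip(titers, titers[1:])):
            raise ValueError("spotted titers must be strictly decreasing")

    @property
    def ladder(self) -> Tuple[float, ...]:
        return tuple(t for t, _ in self.spots)


@dataclass(frozen=True)
class SensitivityCall:
    label: SensitivityLabel
    lowest_positive_titer: Optional[float] = None


@dataclass(frozen=True)
class VariantRecord:
    """A phage-resistant bacterial variant and its provenance."""

    variant_id: str
    parent_strain_id: str
    inducing_phage_id: str
    species: str = ""


class CrossSensitivityMatrix:
    """Resistant-variant x phage grid of sensitive/insensitive/not-tested.

    Invariants enforced at construction: the (variant, inducing phage) cell
    is insensitive whenever tested, and every row has at least one tested
    cell.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        phages: Sequence[str],
        cells: Mapping[Tuple[str, str], CellState],
    ):
        self.variants = tuple(variants)
        self.phages = tuple(phages)
        if not self.phages:
            raise ValueError("empty phage list")
        if not self.variants:
            raise ValueError("empty variant list")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        self._cells = {}
        for (vid, pid), state in cells.items():
            if vid not in set(ids):
                raise ValueError(f"cell references unknown variant {vid!r}")
            if pid not in set(self.phages):
                raise ValueError(f"cell references unknown phage {pid!r}")
            self._cells[(vid, pid)] = CellState(state)
        for v in self.variants:
            row = [self.cell(v.variant_id, p) for p in self.phages]
            if all(s is CellState.NOT_TESTED for s in row):
                raise ValueError(f"variant {v.variant_id} has no tested cell")
            own = self.cell(v.variant_id, v.inducing_phage_id)
            if own is CellState.SENSITIVE:
                raise ValueError(
                    f"variant {v.variant_id} sensitive to its inducing phage"
                )

    def cell(self, variant_id: str, phage_id: str) -> CellState:
        return self._cells.get((variant_id, phage_id), CellState.NOT_TESTED)

    def tested_phages(self, variant_id: str) -> Tuple[str, ...]:
        return tuple(
            p for p in self.phages
            if self.cell(variant_id, p) is not CellState.NOT_TESTED
        )

    def subset(self, variant_ids: Sequence[str]) -> "CrossSensitivityMatrix":
        keep = set(variant_ids)
        variants = [v for v in self.variants if v.variant_id in keep]
        cells = {
            (vid, pid): s for (vid, pid), s in self._cells.items() if vid in keep
        }
        return CrossSensitivityMatrix(variants, self.phages, cells)

    def by_species(self, species: str) -> "CrossSensitivityMatrix":
        return self.subset(
            [v.variant_id for v in self.variants if v.species == species]
        )

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class MutationRecord:
    """One gene-level mutation call in a resistant variant."""

    variant_id: str
    gene: str
    effect: MutationEffect
    product: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect", MutationEffect(self.effect))
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")


@dataclass(frozen=True)
class ReceptorConfirmation:
    phage_id: str
    predicted_receptors: frozenset
    supporting_variants: Tuple[str, ...]
    status: ConfirmationStatus

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "predicted_receptors", frozenset(self.predicted_receptors)
        )
        object.__setattr__(
            self, "supporting_variants", tuple(self.supporting_variants)
        )


@dataclass(frozen=True)
class CocktailDesign:
    """Outcome of coverage-maximizing, receptor-diverse phage selection."""

    selected: Tuple[str, ...]
    coverage: float
    covered_strains: frozenset
    redundancy_depth: Mapping[str, int]
    resilience: Mapping[str, bool]
    core_phages: Tuple[str, ...] = ()
    per_phage_titer: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")


@dataclass(frozen=True)
class StabilitySeries:
    """Per-component cocktail titers over storage months.

    ``component_titers`` maps each component label (species) to a titer
    sequence aligned with ``months``; month 0 is the reference.
    """

    months: Tuple[float, ...]
    component_titers: Mapping[str, Tuple[float, ...]]

    def __post_init__(self) -> None:
        months = tuple(float(m) for m in self.months)
        object.__setattr__(self, "months", months)
        comp = {
            k: tuple(float(x) for x in v) for k, v in self.component_titers.items()
        }
        object.__setattr__(self, "component_titers", comp)
        if not months:
            raise ValueError("empty series")
        if any(m < 0 for m in months):
            raise ValueError("months must be non-negative")
        if not all(a < b for a, b in zip(months, months[1:])):
            raise ValueError("months must be strictly increasing")
        for k, v in comp.items():
            if len(v) != len(months):
                raise ValueError(f"component {k!r} length mismatch")
            if any(x <= 0 for x in v):
                raise ValueError("titers must be positive")

    def final_titers(self) -> Tuple[float, ...]:
        """Summed component titer at each timepoint."""
        comps = list(self.component_titers.values())
        return tuple(float(sum(c[i] for c in comps)) for i in range(len(self.months)))


@dataclass(frozen=True)
class BiofilmMeasurement:
    """OD570 replicates of a treated well set vs the 100% biofilm control."""

    strain_id: str
    assay: str  # "prevention" | "eradication"
    a_ts: Tuple[float, ...]
    a_c100: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "a_ts", tuple(float(x) for x in self.a_ts))
        object.__setattr__(self, "a_c100", tuple(float(x) for x in self.a_c100))
        if self.assay not in ("prevention", "eradication"):
            raise ValueError("assay must be 'prevention' or 'eradication'")
        if not self.a_ts or not self.a_c100:
            raise ValueError("each arm needs at least one replicate")
        if any(x < 0 for x in self.a_ts + self.a_c100):
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class MilkAssayResult:
    """Endpoint CFU/mL replicates for one arm of the milk challenge."""

    strain_id: str
    arm: str  # "phage" | "control"
    endpoint_counts: Tuple[float, ...]
    initial_density: float = 1e4

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "endpoint_counts", tuple(float(x) for x in self.endpoint_counts)
        )
        if self.arm not in ("phage", "control"):
            raise ValueError("arm must be 'phage' or 'control'")
        if not self.endpoint_counts:
            raise ValueError("no replicates")
        if any(x <= 0 for x in self.endpoint_counts):
            raise ValueError("CFU counts must be positive")
        if self.initial_density <= 0:
            raise ValueError("initial density must be positive")


def order_of_magnitude(titer: float) -> int:
    """Band a titer by its order of magnitude: floor(log10(titer))."""
    if titer <= 0:
        raise ValueError("titer must be positive")
    return math.floor(math.log10(titer))
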