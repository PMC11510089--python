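"""Seeded synthetic assay data with the statistical structure the
analysis pipeline assumes.

Generators emulate: logistic bacterial growth with four phage-response
phenotypes, Poisson plaque statistics on dilution plates, spot-test
detection thresholds, receptor-genotype resistance cross-matrices,
strain-specific biofilm capacity with phage suppression, milk endpoint
densities in realistic control ranges, and exponential titer decay during
storage.

Reproducibility: a single global seed fans out to per-assay substreams via
``numpy.random.SeedSequence(seed, spawn_key=(stream, index))`` where
``stream`` is a fixed per-assay integer (see ``STREAMS``); every generator
is bit-reproducible for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import (
    BiofilmMeasurement,
    CellState,
    CrossSensitivityMatrix,
    KineticCurve,
    MilkAssayResult,
    PhageRecord,
    Phenotype,
    PlaqueCountSeries,
    SpotObservation,
    SpotSeries,
    StabilitySeries,
    VariantRecord,
    WellRole,
)

#: fixed per-assay substream indices of the global seed
STREAMS: Mapping[str, int] = {
    "growth": 0,
    "plaque": 1,
    "cross": 2,
    "spot": 3,
    "biofilm": 4,
    "milk": 5,
    "stability": 6,
    "panel": 7,
}


def substream(seed: int, assay: str, index: int = 0) -> np.random.Generator:
    """Independent, reproducible RNG substream for one assay."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(STREAMS[assay], index))
    )


def _default_mix() -> Dict[Phenotype, float]:
    # biofilm-kinetics phenotype counts over the 36 classified strains:
    # 22 fully inhibited, 6 partial, 4 transient, 4 unaffected
    return {
        Phenotype.FULL_INHIBITION: 22 / 36,
        Phenotype.PARTIAL_INHIBITION: 6 / 36,
        Phenotype.TRANSIENT_INHIBITION: 4 / 36,
        Phenotype.NO_EFFECT: 4 / 36,
    }


def _default_ranges() -> Dict[str, Tuple[float, float]]:
    # 24 h untreated milk endpoint ranges (CFU/mL)
    return {"E. coli": (4e7, 2e8), "S. aureus": (3e8, 3e9)}


@dataclass
class SimulationConfig:
    """Stated world of the synthetic assays.

    Defaults mirror the study design: 18 E. coli + 15 S. aureus strains,
    5 + 3 phages, 0.1 mL plated volume, ten-fold dilution steps, the
    observed kinetic-phenotype mix, and the printed untreated milk endpoint
    ranges. ``noise_sd_od`` (absorbance units) is a package default; the
    source assays report no within-replicate variance.
    """

    seed: int = 0
    n_strains_per_species: Mapping[str, int] = field(
        default_factory=lambda: {"E. coli": 18, "S. aureus": 15}
    )
    n_phages: Mapping[str, int] = field(
        default_factory=lambda: {"E. coli": 5, "S. aureus": 3}
    )
    noise_sd_od: float = 0.02
    plate_volume_ml: float = 0.1
    dilution_step: float = 10.0
    phenotype_mix: Mapping[Phenotype, float] = field(default_factory=_default_mix)
    control_endpoint_ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=_default_ranges
    )

    def __post_init__(self) -> None:
        total = sum(self.phenotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phenotype_mix must sum to 1 (got {total})")
        if self.noise_sd_od < 0:
            raise ValueError("noise_sd_od must be non-negative")
        for k, n in {**self.n_strains_per_species, **self.n_phages}.items():
            if n <= 0:
                raise ValueError(f"count for {k!r} must be positive")
        if self.plate_volume_ml <= 0:
            raise ValueError("plate volume must be positive")
        if self.dilution_step <= 1:
            raise ValueError("dilution step must exceed 1")


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

#: 4-parameter logistic defaults (OD units / minutes); plateau is drawn
#: uniformly from this interval when not fixed
LOGISTIC_BASELINE = 0.05
LOGISTIC_PLATEAU_RANGE = (0.9, 1.3)
LOGISTIC_RATE = 0.05  # 1/min
LOGISTIC_MIDPOINT = 110.0  # min
TRANSIENT_LAG = 80.0  # min; delay before a transient strain rejoins control
PARTIAL_PLATEAU_FACTOR = 0.45  # reduced carrying capacity under phage


def _logistic(t: np.ndarray, baseline: float, plateau: float, rate: float, mid: float):
    return baseline + (plateau - baseline) / (1.0 + np.exp(-rate * (t - mid)))


def simulate_growth_curve(
    phenotype: Phenotype | str,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    duration_min: float = 280.0,
    step_min: float = 20.0,
    plateau: Optional[float] = None,
) -> Tuple[KineticCurve, KineticCurve]:
    """Simulate a (control, treated) kinetic curve pair for one phenotype.

    The control follows logistic growth; the treated curve depends on the
    phenotype: full inhibition stays at baseline, partial inhibition grows
    to a reduced plateau, transient inhibition lags behind and rejoins the
    control kinetics, no-effect matches the control within noise. Gaussian
    noise of sd ``config.noise_sd_od`` is added to every point (floored at
    zero). The default 0-280 min / 20 min grid matches the lytic assay;
    pass ``duration_min=1440`` for 24 h biofilm kinetics.
    """
    phenotype = Phenotype(phenotype)
    rng = rng if rng is not None else substream(config.seed, "growth")
    t = np.arange(0.0, duration_min + 0.5 * step_min, step_min)
    if plateau is None:
        plateau = float(rng.uniform(*LOGISTIC_PLATEAU_RANGE))
    control = _logistic(t, LOGISTIC_BASELINE, plateau, LOGISTIC_RATE, LOGISTIC_MIDPOINT)

    if phenotype is Phenotype.FULL_INHIBITION:
        treated = np.full_like(t, LOGISTIC_BASELINE)
    elif phenotype is Phenotype.PARTIAL_INHIBITION:
        treated = _logistic(
            t,
            LOGISTIC_BASELINE,
            LOGISTIC_BASELINE + PARTIAL_PLATEAU_FACTOR * (plateau - LOGISTIC_BASELINE),
            LOGISTIC_RATE,
            LOGISTIC_MIDPOINT,
        )
    elif phenotype is Phenotype.TRANSIENT_INHIBITION:
        treated = _logistic(
            t, LOGISTIC_BASELINE, plateau, LOGISTIC_RATE, LOGISTIC_MIDPOINT + TRANSIENT_LAG
        )
    elif phenotype is Phenotype.NO_EFFECT:
        treated = control.copy()
    else:  # pragma: no cover - Phenotype() already validates
        raise ValueError(f"unknown phenotype {phenotype!r}")

    if config.noise_sd_od > 0:
        control = control + rng.normal(0.0, config.noise_sd_od, t.size)
        treated = treated + rng.normal(0.0, config.noise_sd_od, t.size)
    control = np.clip(control, 0.0, None)
    treated = np.clip(treated, 0.0, None)
    return (
        KineticCurve(t, control, role=WellRole.POSITIVE_CONTROL),
        KineticCurve(t, treated, role=WellRole.TEST),
    )


# ---------------------------------------------------------------------------
# plaque counts
# ---------------------------------------------------------------------------

def simulate_plaque_counts(
    true_titer: float,
    dilutions: Sequence[float],
    plates_per_dilution: int = 1,
    volume_ml: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> PlaqueCountSeries:
    """Poisson plaque counts: each plate ~ Poisson(titer * volume * dilution)."""
    if true_titer <= 0:
        raise ValueError("true titer must be positive")
    if volume_ml <= 0:
        raise ValueError("plated volume must be positive")
    if plates_per_dilution < 1:
        raise ValueError("need at least one plate per dilution")
    for d in dilutions:
        if not (0 < d <= 1):
            raise ValueError(f"dilution factor {d} outside (0, 1]")
    if rng is None:
        rng = substream(seed if seed is not None else 0, "plaque")
    records = []
    for d in dilutions:
        mean = true_titer * volume_ml * d
        counts = tuple(int(c) for c in rng.poisson(mean, plates_per_dilution))
        records.append((d, counts))
    return PlaqueCountSeries(records=tuple(records), volume_ml=volume_ml)


# ---------------------------------------------------------------------------
# receptor genotypes and cross-sensitivity matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReceptorGenotype:
    """A wild-type strain's intact receptor-class repertoire."""

    strain_id: str
    intact_receptors: frozenset
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intact_receptors", frozenset(self.intact_receptors)
        )
        if not self.intact_receptors:
            raise ValueError("wild-type strain must carry at least one receptor")


def simulate_cross_matrix(
    genotypes: Sequence[ReceptorGenotype],
    phages: Sequence[PhageRecord],
    seed: int = 0,
) -> CrossSensitivityMatrix:
    """Resistance cross-matrix from a receptor-loss genotype model.

    For each (genotype, phage) pair a resistant variant is derived by
    knocking out the inducing phage's main receptor class(es) present in
    the genotype; the variant is then sensitive to a phage iff at least one
    of that phage's main receptor classes remains intact. Deterministic
    given the seed (the RNG only orders knockouts when a phage lists
    several main receptors, all of which are removed so the variant is
    guaranteed insensitive to its inducing phage).
    """
    if not phages:
        raise ValueError("empty phage list")
    if not genotypes:
        raise ValueError("empty genotype list")
    rng = substream(seed, "cross")
    phage_ids = [p.phage_id for p in phages]
    alphabet = set().union(*(g.intact_receptors for g in genotypes))
    for p in phages:
        if not p.main_receptors:
            raise ValueError(f"phage {p.phage_id} lacks main-receptor annotation")
        if not p.main_receptors <= alphabet:
            raise ValueError(
                f"phage {p.phage_id} main receptors outside the genotype alphabet"
            )

    variants: List[VariantRecord] = []
    cells: Dict[Tuple[str, str], CellState] = {}
    for g in genotypes:
        order = rng.permutation(len(phages))  # seeded, order-stable variant naming
        for idx in order:
            inducer = phages[int(idx)]
            knocked = inducer.main_receptors & g.intact_receptors
            if not knocked:
                continue  # phage cannot infect this genotype; no variant arises
            intact = g.intact_receptors - knocked
            vid = f"{g.strain_id}-r{inducer.short_name or inducer.phage_id}"
            variants.append(
                VariantRecord(
                    variant_id=vid,
                    parent_strain_id=g.strain_id,
                    inducing_phage_id=inducer.phage_id,
                    species=g.species,
                )
            )
            for q in phages:
                same_species = (not q.host_species or not g.species
                                or q.host_species == g.species)
                if not same_species:
                    cells[(vid, q.phage_id)] = CellState.NOT_TESTED
                elif q.main_receptors & intact:
                    cells[(vid, q.phage_id)] = CellState.SENSITIVE
                else:
                    cells[(vid, q.phage_id)] = CellState.INSENSITIVE
    variants.sort(key=lambda v: v.variant_id)
    return CrossSensitivityMatrix(variants, phage_ids, cells)


# ---------------------------------------------------------------------------
# spot grids
# ---------------------------------------------------------------------------

#: ten-fold cocktail dilution ladder used in the host-range assay (PFU/mL)
DEFAULT_SPOT_LADDER: Tuple[float, ...] = (2e8, 2e7, 2e6, 2e5, 2e4, 2e3)


def simulate_spot_grid(
    detection_thresholds: Mapping[str, float],
    ladder: Sequence[float] = DEFAULT_SPOT_LADDER,
    replicates: int = 3,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Dict[str, List[SpotSeries]]:
    """Spot-test grids: a spot is positive iff its titer meets the strain's
    detection threshold (infinite threshold = insensitive strain).

    The lowest positive dilution reads as discrete plaques (P), higher
    positive titers as clearance (CL).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if rng is None:
        rng = substream(seed if seed is not None else 0, "spot")
    out: Dict[str, List[SpotSeries]] = {}
    for strain, threshold in detection_thresholds.items():
        series = []
        for r in range(replicates):
            spots = []
            positives = [t for t in ladder if t >= threshold]
            lowest_pos = min(positives) if positives else None
            for t in ladder:
                if lowest_pos is not None and t >= threshold:
                    obs = (
                        SpotObservation.P if t == lowest_pos else SpotObservation.CL
                    )
                else:
                    obs = SpotObservation.NL
                spots.append((t, obs))
            series.append(
                SpotSeries(strain_id=strain, spots=tuple(spots), replicate_id=f"r{r+1}")
            )
        out[strain] = series
    return out


# ---------------------------------------------------------------------------
# biofilm plates
# ---------------------------------------------------------------------------

def simulate_biofilm_plate(
    strain_capacities: Mapping[str, float],
    suppression: Mapping[str, float],
    assay: str = "prevention",
    baseline_od: float = 0.8,
    noise_sd: float = 0.03,
    replicates: int = 3,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> List[BiofilmMeasurement]:
    """MTT biofilm plate: absorbance = baseline x capacity x suppression + noise.

    ``suppression`` is the residual biofilm fraction under phage (0 = fully
    prevented, 1 = unaffected); the untreated control omits it.
    """
    if rng is None:
        rng = substream(seed if seed is not None else 0, "biofilm")
    out = []
    for strain, capacity in strain_capacities.items():
        if capacity < 0:
            raise ValueError("biofilm capacity must be non-negative")
        s = suppression[strain]
        signal = baseline_od * capacity
        a_c100 = np.clip(rng.normal(signal, noise_sd, replicates), 0.0, None)
        a_ts = np.clip(rng.normal(signal * s, noise_sd, replicates), 0.0, None)
        out.append(
            BiofilmMeasurement(
                strain_id=strain, assay=assay, a_ts=tuple(a_ts), a_c100=tuple(a_c100)
            )
        )
    return out


# ---------------------------------------------------------------------------
# milk endpoints
# ---------------------------------------------------------------------------

def milk_control_log10_mean(config: SimulationConfig, species: str) -> float:
    """Geometric-mean log10 of the species' untreated endpoint range."""
    lo, hi = config.control_endpoint_ranges[species]
    return 0.5 * (np.log10(lo) + np.log10(hi))


def simulate_milk_counts(
    strain_id: str,
    species: str,
    config: SimulationConfig,
    reduction_percent: float = 43.0,
    n_replicates: int = 4,
    sd_log10: float = 0.15,
    initial_density: float = 1e4,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[MilkAssayResult, MilkAssayResult]:
    """Paired (phage, control) milk endpoints with a planted %log reduction.

    Control endpoints are lognormal around the species' printed untreated
    range; the phage arm's log10 mean is scaled by (1 - reduction/100).
    """
    rng = rng if rng is not None else substream(config.seed, "milk")
    mu_c = milk_control_log10_mean(config, species)
    mu_p = mu_c * (1.0 - reduction_percent / 100.0)
    lc = rng.normal(mu_c, sd_log10, n_replicates)
    lp = rng.normal(mu_p, sd_log10, n_replicates)
    control = MilkAssayResult(
        strain_id=strain_id,
        arm="control",
        endpoint_counts=tuple(10.0**lc),
        initial_density=initial_density,
    )
    phage = MilkAssayResult(
        strain_id=strain_id,
        arm="phage",
        endpoint_counts=tuple(10.0**lp),
        initial_density=initial_density,
    )
    return phage, control


# ---------------------------------------------------------------------------
# storage stability
# ---------------------------------------------------------------------------

#: per-month exponential decay rates back-calculated once from the 24-month
#: storage endpoints of the two cocktail components
DEFAULT_DECAY_PER_MONTH: Mapping[str, float] = {
    "E. coli": 0.030,
    "S. aureus": 0.055,
}


def simulate_stability_series(
    initial_titers: Mapping[str, float],
    months: Sequence[float] = tuple(range(0, 25, 3)),
    decay_per_month: Mapping[str, float] | float = DEFAULT_DECAY_PER_MONTH,
    noise_sd_log10: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> StabilitySeries:
    """Exponential titer decay with lognormal measurement noise.

    titer(t) = T0 * exp(-lambda * t) * 10**N(0, noise_sd_log10); the
    reference month-0 measurement is noiseless by convention.
    ``decay_per_month`` may be one shared rate or a per-component mapping;
    components absent from the mapping decay at 0.04/month.
    """
    if rng is None:
        rng = substream(seed if seed is not None else 0, "stability")
    comp = {}
    for species, t0 in initial_titers.items():
        if t0 <= 0:
            raise ValueError("initial titer must be positive")
        if isinstance(decay_per_month, (int, float)):
            lam = float(decay_per_month)
        else:
            lam = decay_per_month.get(species, 0.04)
        vals = []
        for i, m in enumerate(months):
            mean = t0 * np.exp(-lam * m)
            noise = 10.0 ** rng.normal(0.0, noise_sd_log10) if i > 0 else 1.0
            vals.append(mean * noise)
        comp[species] = tuple(vals)
    return StabilitySeries(months=tuple(months), component_titers=comp)


# ---------------------------------------------------------------------------
# whole-campaign preset
# ---------------------------------------------------------------------------

#: receptor alphabet of the generative model
RECEPTOR_ALPHABET = (
    "OmpC",
    "OmpA",
    "LPS-core-A",
    "LPS-core-B",
    "WTA-beta-GlcNAc",
    "WTA-alpha-GlcNAc",
)


def paper_shape_panel(config: SimulationConfig) -> List[PhageRecord]:
    """A synthetic 5 + 3 phage panel with receptor-diverse annotations.

    Mirrors the shape of the study panel: anti-E. coli phages split across
    two LPS core types plus distinct porins, anti-S. aureus phages across
    beta/alpha WTA GlcNAc decorations.
    """
    ecoli = [
        PhageRecord("phiEc1", "E. coli", main_receptors={"OmpC"},
                    support_receptors={"LPS-core-A"}, short_name="Ec1"),
        PhageRecord("phiEc2", "E. coli", main_receptors={"OmpC"},
                    support_receptors={"LPS-core-B"}, short_name="Ec2"),
        PhageRecord("phiEc3", "E. coli", main_receptors={"OmpA"},
                    support_receptors={"LPS-core-A"}, short_name="Ec3"),
        PhageRecord("phiEc4", "E. coli", main_receptors={"LPS-core-B"},
                    short_name="Ec4"),
        PhageRecord("phiEc5", "E. coli", main_receptors={"LPS-core-A"},
                    short_name="Ec5"),
    ]
    saur = [
        PhageRecord("phiSa1", "S. aureus", main_receptors={"WTA-beta-GlcNAc"},
                    short_name="Sa1"),
        PhageRecord("phiSa2", "S. aureus", main_receptors={"WTA-beta-GlcNAc"},
                    support_receptors={"WTA-alpha-GlcNAc"}, short_name="Sa2"),
        PhageRecord("phiSa3", "S. aureus", main_receptors={"WTA-alpha-GlcNAc"},
                    short_name="Sa3"),
    ]
    return ecoli[: config.n_phages.get("E. coli", 5)] + saur[
        : config.n_phages.get("S. aureus", 3)
    ]


def paper_shape_genotypes(config: SimulationConfig) -> List[ReceptorGenotype]:
    """Wild-type receptor genotypes for the configured strain collection."""
    rng = substream(config.seed, "panel")
    out = []
    for species, n in config.n_strains_per_species.items():
        pool = (
            ("OmpC", "OmpA", "LPS-core-A", "LPS-core-B")
            if species == "E. coli"
            else ("WTA-beta-GlcNAc", "WTA-alpha-GlcNAc")
        )
        prefix = "Ec" if species == "E. coli" else "Sa"
        for i in range(n):
            k = int(rng.integers(max(1, len(pool) - 1), len(pool) + 1))
            intact = frozenset(
                rng.choice(pool, size=min(k, len(pool)), replace=False).tolist()
            )
            out.append(
                ReceptorGenotype(
                    strain_id=f"{prefix}{i+1:03d}",
                    intact_receptors=intact,
                    species=species,
                )
            )
    return out
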