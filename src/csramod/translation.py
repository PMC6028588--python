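"""Translation-initiation free energies and CsrA regulation calls.

A deliberately simple ribosome-binding free-energy model in the spirit of
thermodynamic RBS calculators.  For the free mRNA,

    dG_total,free = (dG_mRNA:rRNA + dG_start + dG_spacing + dG_standby)
                    - dG_initial

where dG_mRNA:rRNA is the SD:anti-SD hybridization energy (best duplex in a
window upstream of the start codon), dG_start the start-codon recognition
term, dG_spacing a non-negative penalty for sub-optimal aligned spacing,
dG_standby the mRNA's residual fold energy with the ribosome footprint (SD
region + start codon + first 13 nt of CDS) forced single-stranded, and
dG_initial the unconstrained MFE fold.  The standby-minus-initial difference
is exactly the cost of melting structure out of the footprint.

For a CsrA-bound conformation the initial state is the conformation's
constrained fold (both CsrA footprints single-stranded); in the final state
the ribosome footprint and any surviving (non-evicted) CsrA site must both
be unpaired, and the cost of evicting a CsrA whose site overlaps the
footprint -- the lost site energy plus, when the pair is broken, the lost
cooperativity -- is charged to the hybridization term.

Translation rates follow r ~ exp(-beta * dG_total) with the empirical rate
constant beta = 0.45 /(kcal/mol); the per-conformation ratio
R_i = r_free / r_CsrA,i is classified as repressed (R > 1.2), activated
(R < 0.8), or not impacted.  The ensemble verdict is the label whose summed
scaled probability is at least 1.8-fold larger than each alternative;
otherwise regulation is heterogeneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .energy import RT_KCAL
from .ensemble import Conformation, Ensemble
from .folding import FoldCache, FoldingEngine
from .records import MRNARecord

__all__ = [
    "TranslationParams",
    "TranslationEnergyBreakdown",
    "ConformationCall",
    "RegulationCall",
    "ribosome_energy_free",
    "ribosome_energy_bound",
    "classify_conformation",
    "call_ensemble_regulation",
    "regulate_record",
    "BETA_RATE_PER_RT",
]

#: Empirical translation-rate Boltzmann factor, 0.45 /(kcal/mol), converted
#: to per-RT units at 37 degC.
BETA_RATE_PER_RT = 0.45 * RT_KCAL

REPRESSED, ACTIVATED, NOT_IMPACTED = "repressed", "activated", "not_impacted"
LABELS = (REPRESSED, ACTIVATED, NOT_IMPACTED)


@dataclass
class TranslationParams:
    """Tunable constants of the simplified ribosome-binding model.

    Defaults are drawn from the thermodynamic RBS-calculator literature;
    energies in RT unless noted.
    """

    anti_sd: str = "ACCUCCUUA"  # 3' tail of the 16S rRNA, written 5'->3'
    sd_search_window: int = 25  # nt upstream of the start codon searched for SD
    start_codon_energies: dict[str, float] = field(
        default_factory=lambda: {"AUG": -1.94, "GUG": -0.12, "UUG": -0.07}
    )
    optimal_spacing: int = 5  # nt between SD 3' pairing end and start codon
    spacing_stretch: float = 0.078  # RT/nt^2 penalty for spacing > optimum
    spacing_compress: float = 0.41  # RT/nt^2 penalty for spacing < optimum
    spacing_cap: float = 12.0  # RT ceiling on the spacing penalty
    footprint_upstream: int = 15  # footprint reach upstream of the start codon
    footprint_downstream: int = 16  # start codon (3) + first 13 nt of CDS
    repression_threshold: float = 1.2
    activation_threshold: float = 0.8
    heterogeneity_factor: float = 1.8
    beta_rate: float = BETA_RATE_PER_RT


@dataclass(frozen=True)
class TranslationEnergyBreakdown:
    """Ribosome-binding free-energy terms (RT) for one mRNA state."""

    dG_mRNA_rRNA: float
    dG_start: float
    dG_spacing: float
    dG_standby: float
    dG_initial: float
    sd_spacing: int | None = None  # aligned spacing used, nt (None: no SD duplex)
    truncated_window: bool = False  # SD search window clipped at the 5' end

    @property
    def dG_total(self) -> float:
        return (
            self.dG_mRNA_rRNA + self.dG_start + self.dG_spacing + self.dG_standby
        ) - self.dG_initial


def footprint_interval(record: MRNARecord, params: TranslationParams) -> tuple[int, int]:
    """Half-open interval of the ribosome footprint on the analysis window."""
    lo = max(0, record.cds_start - params.footprint_upstream)
    hi = min(len(record.sequence), record.cds_start + params.footprint_downstream)
    return lo, hi


def _spacing_penalty(spacing: int, params: TranslationParams) -> float:
    delta = spacing - params.optimal_spacing
    coeff = params.spacing_stretch if delta >= 0 else params.spacing_compress
    return min(coeff * delta * delta, params.spacing_cap)


def _hybridization(
    record: MRNARecord, engine, params: TranslationParams
) -> tuple[float, float, int | None, bool]:
    """(dG_mRNA_rRNA, dG_spacing, spacing, truncated) for the best SD duplex."""
    lo = record.cds_start - params.sd_search_window
    truncated = lo < 0
    lo = max(0, lo)
    window = record.sequence[lo : record.cds_start]
    if len(window) < 4:
        return 0.0, 0.0, None, truncated
    base = engine.engine if isinstance(engine, FoldCache) else engine
    energy, last_paired = base.duplex_energy(window, params.anti_sd)
    if last_paired is None:
        return 0.0, 0.0, None, truncated
    spacing = len(window) - 1 - last_paired
    return energy, _spacing_penalty(spacing, params), spacing, truncated


def _start_energy(record: MRNARecord, params: TranslationParams) -> float:
    return params.start_codon_energies.get(record.start_codon, 0.0)


def ribosome_energy_free(
    record: MRNARecord,
    engine: FoldingEngine | FoldCache,
    params: TranslationParams | None = None,
) -> TranslationEnergyBreakdown:
    """Ribosome-binding free energy of the CsrA-free mRNA."""
    params = params or TranslationParams()
    if not isinstance(engine, FoldCache):
        engine = FoldCache(engine)
    hyb, spacing_pen, spacing, truncated = _hybridization(record, engine, params)
    lo, hi = footprint_interval(record, params)
    footprint = range(lo, hi)
    return TranslationEnergyBreakdown(
        dG_mRNA_rRNA=hyb,
        dG_start=_start_energy(record, params),
        dG_spacing=spacing_pen,
        dG_standby=engine.fold(record.sequence, footprint).free_energy,
        dG_initial=engine.fold(record.sequence).free_energy,
        sd_spacing=spacing,
        truncated_window=truncated,
    )


def ribosome_energy_bound(
    record: MRNARecord,
    conformation: Conformation,
    engine: FoldingEngine | FoldCache,
    params: TranslationParams | None = None,
) -> TranslationEnergyBreakdown:
    """Ribosome-binding free energy with a CsrA homodimer bound in *conformation*.

    Sites overlapping the ribosome footprint are evicted: their site energy
    and, since the two-site pair is then broken, the cooperativity term are
    charged as an eviction cost.  Sites outside the footprint stay bound and
    must remain single-stranded in the final state.  The initial state is
    the conformation's constrained fold (both sites single-stranded).
    """
    params = params or TranslationParams()
    if not isinstance(engine, FoldCache):
        engine = FoldCache(engine)
    hyb, spacing_pen, spacing, truncated = _hybridization(record, engine, params)
    lo, hi = footprint_interval(record, params)

    sites = (conformation.site1, conformation.site2)
    evicted = [s for s in sites if s.start < hi and s.end > lo]
    surviving = [s for s in sites if s not in evicted]
    eviction_cost = 0.0
    if evicted:
        eviction_cost -= sum(s.dG_site for s in evicted)
        eviction_cost -= conformation.dG_coop  # the pair is broken either way

    final_constraint: set[int] = set(range(lo, hi))
    for s in surviving:
        final_constraint.update(range(s.start, s.end))
    bound_constraint: set[int] = set()
    for s in sites:
        bound_constraint.update(range(s.start, s.end))

    return TranslationEnergyBreakdown(
        dG_mRNA_rRNA=hyb + eviction_cost,
        dG_start=_start_energy(record, params),
        dG_spacing=spacing_pen,
        dG_standby=engine.fold(record.sequence, final_constraint).free_energy,
        dG_initial=engine.fold(record.sequence, bound_constraint).free_energy,
        sd_spacing=spacing,
        truncated_window=truncated,
    )


@dataclass(frozen=True)
class ConformationCall:
    rank: int
    R: float
    label: str
    scaled_p: float
    dG_total_free: float
    dG_total_bound: float


@dataclass(frozen=True)
class RegulationCall:
    record_id: str
    verdict: str  # repressed | activated | no_impact | heterogeneous | not_assessable
    label_mass: dict[str, float]
    calls: list[ConformationCall]


def classify_conformation(
    free: TranslationEnergyBreakdown,
    bound: TranslationEnergyBreakdown,
    params: TranslationParams | None = None,
) -> tuple[float, str]:
    """Rate ratio R_i = r_free / r_CsrA,i and its regulatory label.

    R_i = exp(beta_rate * (dG_total,CsrA - dG_total,free)); it depends only
    on the energy difference.  Non-finite energies raise a ValueError (the
    caller drops the conformation with a diagnostic).
    """
    params = params or TranslationParams()
    gap = bound.dG_total - free.dG_total
    if not math.isfinite(gap):
        raise ValueError(f"non-finite energy gap {gap!r}")
    r = math.exp(min(params.beta_rate * gap, 700.0))
    if r > params.repression_threshold:
        label = REPRESSED
    elif r < params.activation_threshold:
        label = ACTIVATED
    else:
        label = NOT_IMPACTED
    return r, label


def call_ensemble_regulation(
    calls: list[tuple[str, float]], heterogeneity_factor: float = 1.8
) -> tuple[str, dict[str, float]]:
    """Ensemble verdict from (label, scaled_p) pairs over the top-K.

    The label with the largest summed probability represents the ensemble
    only if its mass is at least *heterogeneity_factor* times each of the
    other two masses (boundary inclusive); otherwise the regulation mode is
    heterogeneous.  An empty call list is not assessable.
    """
    if not calls:
        return "not_assessable", {label: 0.0 for label in LABELS}
    mass = {label: 0.0 for label in LABELS}
    for label, p in calls:
        if label not in mass:
            raise ValueError(f"unknown regulation label {label!r}")
        mass[label] += p
    leader = max(LABELS, key=lambda lbl: mass[lbl])
    others = [mass[lbl] for lbl in LABELS if lbl != leader]
    if all(mass[leader] >= heterogeneity_factor * m for m in others):
        verdict = {"repressed": "repressed", "activated": "activated", "not_impacted": "no_impact"}[leader]
    else:
        verdict = "heterogeneous"
    return verdict, mass


def regulate_record(
    record: MRNARecord,
    ensemble: Ensemble,
    engine: FoldingEngine | FoldCache,
    params: TranslationParams | None = None,
) -> RegulationCall:
    """Full per-record regulation call over the top-K conformations."""
    params = params or TranslationParams()
    if not isinstance(engine, FoldCache):
        engine = FoldCache(engine)
    if not ensemble.top_k:
        return RegulationCall(
            record_id=record.id,
            verdict="not_assessable",
            label_mass={label: 0.0 for label in LABELS},
            calls=[],
        )
    free = ribosome_energy_free(record, engine, params)
    calls: list[ConformationCall] = []
    for rank, conf in enumerate(ensemble.top_k, start=1):
        bound = ribosome_energy_bound(record, conf, engine, params)
        r, label = classify_conformation(free, bound, params)
        calls.append(
            ConformationCall(
                rank=rank,
                R=r,
                label=label,
                scaled_p=conf.scaled_p,
                dG_total_free=free.dG_total,
                dG_total_bound=bound.dG_total,
            )
        )
    verdict, mass = call_ensemble_regulation(
        [(c.label, c.scaled_p) for c in calls], params.heterogeneity_factor
    )
    return RegulationCall(record_id=record.id, verdict=verdict, label_mass=mass, calls=calls)
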