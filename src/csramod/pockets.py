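"""Binding-site pockets and ensemble contingency statistics.

A pocket is a maximal run of predicted binding sites that overlap, are
adjacent, or have at most one nucleotide between them.  Pockets are built
from the unique sites appearing in the top-K conformations (with per-site
occurrence counts), and pockets containing 7-10 non-consensus (non-ANGGN)
members are flagged as candidate extended regions of weak, "flexible" CsrA
binding.  Conformations are also classified by high-affinity-site count,
strong cooperativity, and large structural change, and the resulting
contingency table is scored with exact hypergeometric tail tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .energy import SITE_LENGTH, BindingSite
from .ensemble import Conformation, Ensemble
from .records import MRNARecord
from .translation import TranslationParams

__all__ = [
    "Pocket",
    "ConformationClassification",
    "ContingencyCounts",
    "build_pockets",
    "flag_flexible_pockets",
    "classify_conformation_terms",
    "classify_conformations",
    "hypergeometric_enrichment",
    "sd_overlap_report",
]

#: Maximum nucleotide gap between consecutive member-site windows of a pocket.
POCKET_GAP = 1

STRONG_COOP_ENERGY = -4.0  # RT
STRONG_COOP_MAX_D = 25  # nt (exclusive)
LARGE_STRUCTURE_CHANGE = 3.0  # RT


@dataclass
class Pocket:
    """A contiguous run of predicted sites, numbered 5'->3'."""

    index: int
    sites: list[BindingSite]  # unique members, sorted by start
    occurrences: dict[tuple[int, str], int]  # appearances across top-K conformations
    flexible_flag: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.sites[0].start, self.sites[-1].end

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_consensus(self) -> int:
        return sum(s.is_high_affinity for s in self.sites)

    @property
    def n_nonconsensus(self) -> int:
        return self.n_sites - self.n_consensus


def build_pockets(top_k_conformations: list[Conformation]) -> list[Pocket]:
    """Group the unique sites of the top-K conformations into pockets.

    Sites are deduplicated by (start, sequence) with occurrence counts, then
    single-linkage chained: a site joins the current pocket when the gap
    between its window and the previous window is at most one nucleotide.
    """
    counts: dict[tuple[int, str], int] = {}
    by_key: dict[tuple[int, str], BindingSite] = {}
    for conf in top_k_conformations:
        for site in (conf.site1, conf.site2):
            key = (site.start, site.sequence)
            counts[key] = counts.get(key, 0) + 1
            by_key[key] = site
    unique = sorted(by_key.values(), key=lambda s: (s.start, s.sequence))
    pockets: list[Pocket] = []
    current: list[BindingSite] = []
    current_end = -(10**9)
    for site in unique:
        if current and site.start > current_end + POCKET_GAP:
            pockets.append(_make_pocket(len(pockets) + 1, current, counts))
            current = []
            current_end = -(10**9)
        current.append(site)
        current_end = max(current_end, site.end)
    if current:
        pockets.append(_make_pocket(len(pockets) + 1, current, counts))
    return pockets


def _make_pocket(index: int, sites: list[BindingSite], counts) -> Pocket:
    keys = [(s.start, s.sequence) for s in sites]
    return Pocket(index=index, sites=list(sites), occurrences={k: counts[k] for k in keys})


def flag_flexible_pockets(
    pockets: list[Pocket], low: int = 7, high: int = 10
) -> list[Pocket]:
    """Flag pockets with *low*-*high* non-consensus members (inclusive) as
    potential extended regions of low-affinity CsrA interaction.  Pockets
    with more than *high* non-consensus sites are left unflagged."""
    for p in pockets:
        p.flexible_flag = low <= p.n_nonconsensus <= high
    return pockets


@dataclass(frozen=True)
class ConformationClassification:
    n_high_affinity: int  # 0, 1 or 2 ANGGN sites in the pair
    strong_cooperativity: bool  # dG_coop <= -4.0 RT and d < 25 nt
    large_structural_change: bool  # ddG_unfold >= 3.0 RT


def classify_conformation_terms(
    conf: Conformation,
    coop_energy: float = STRONG_COOP_ENERGY,
    coop_max_d: int = STRONG_COOP_MAX_D,
    structure_change: float = LARGE_STRUCTURE_CHANGE,
) -> ConformationClassification:
    return ConformationClassification(
        n_high_affinity=conf.n_high_affinity,
        strong_cooperativity=conf.dG_coop <= coop_energy and conf.d < coop_max_d,
        large_structural_change=conf.ddG_unfold >= structure_change,
    )


@dataclass
class ContingencyCounts:
    """Cohort-level counts per stratum (all / 2 / 1 / 0 high-affinity sites)."""

    total: int = 0
    total_structure: int = 0
    total_coop: int = 0
    strata: dict[int, dict[str, int]] = field(
        default_factory=lambda: {
            n: {"total": 0, "structure": 0, "coop": 0} for n in (0, 1, 2)
        }
    )

    def add(self, cls: ConformationClassification) -> None:
        self.total += 1
        self.total_structure += cls.large_structural_change
        self.total_coop += cls.strong_cooperativity
        row = self.strata[cls.n_high_affinity]
        row["total"] += 1
        row["structure"] += cls.large_structural_change
        row["coop"] += cls.strong_cooperativity


def classify_conformations(ensembles: list[Ensemble], **thresholds) -> ContingencyCounts:
    """Aggregate top-K conformations of a cohort into contingency counts."""
    counts = ContingencyCounts()
    for ens in ensembles:
        for conf in ens.top_k:
            counts.add(classify_conformation_terms(conf, **thresholds))
    return counts


def hypergeometric_enrichment(
    population: int, successes: int, sample: int, observed: int, tail: str
) -> float:
    """Exact hypergeometric tail probability via stable log-space summation.

    ``tail="upper"`` gives P(X >= observed) (enrichment); ``tail="lower"``
    gives P(X <= observed) (depletion), for X ~ Hypergeom(population,
    successes, sample).
    """
    N, K, n, k = population, successes, sample, observed
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= n and k <= K):
        raise ValueError(
            f"impossible counts: population={N}, successes={K}, sample={n}, observed={k}"
        )
    if tail not in ("upper", "lower"):
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    k_lo = max(0, n - (N - K))
    k_hi = min(n, K)
    if tail == "upper":
        ks = np.arange(max(k, k_lo), k_hi + 1)
    else:
        ks = np.arange(k_lo, min(k, k_hi) + 1)
    if ks.size == 0:
        return 0.0
    logpmf = (
        gammaln(K + 1)
        - gammaln(ks + 1)
        - gammaln(K - ks + 1)
        + gammaln(N - K + 1)
        - gammaln(n - ks + 1)
        - gammaln(N - K - n + ks + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def hypergeometric_point_probability(
    population: int, successes: int, sample: int, observed: int
) -> float:
    """Hypergeometric probability mass at exactly *observed* successes.

    Provided alongside the tail tests because published contingency analyses
    of this kind sometimes report the non-cumulative (point) probability;
    prefer :func:`hypergeometric_enrichment` for actual inference.
    """
    N, K, n, k = population, successes, sample, observed
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= n and k <= K):
        raise ValueError(
            f"impossible counts: population={N}, successes={K}, sample={n}, observed={k}"
        )
    logpmf = (
        gammaln(K + 1)
        - gammaln(k + 1)
        - gammaln(K - k + 1)
        + gammaln(N - K + 1)
        - gammaln(n - k + 1)
        - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(np.exp(logpmf))


def sd_region(record: MRNARecord, params: TranslationParams | None = None) -> tuple[int, int]:
    """Shine-Dalgarno region, operationalized as 5-15 nt upstream of the start
    codon: the half-open interval [cds_start-15, cds_start-5)."""
    return max(0, record.cds_start - 15), max(0, record.cds_start - 5)


def _overlaps(site: BindingSite, lo: int, hi: int) -> bool:
    return site.start < hi and site.end > lo


def sd_overlap_report(
    records: list[MRNARecord],
    ensembles: list[Ensemble],
    params: TranslationParams | None = None,
) -> dict:
    """Cohort summary of where the most-likely conformation's sites fall.

    Per record: does any site of the rank-1 conformation overlap the SD
    region by >= 1 nt, overlap the start codon by >= 1 nt, both, or neither.
    """
    by_id = {e.record_id: e for e in ensembles}
    rows = []
    for rec in records:
        ens = by_id.get(rec.id)
        if ens is None or not ens.top_k:
            continue
        top = ens.top_k[0]
        sd_lo, sd_hi = sd_region(rec, params)
        start_lo, start_hi = rec.cds_start, rec.cds_start + 3
        sites = (top.site1, top.site2)
        sd = any(_overlaps(s, sd_lo, sd_hi) for s in sites)
        start = any(_overlaps(s, start_lo, start_hi) for s in sites)
        rows.append(
            {
                "record_id": rec.id,
                "sd_overlap": sd,
                "start_overlap": start,
                "both": sd and start,
                "neither": not sd and not start,
            }
        )
    n = len(rows)
    summary = {"n_records": n, "rows": rows}
    for key in ("sd_overlap", "start_overlap", "both", "neither"):
        count = sum(r[key] for r in rows)
        summary[f"pct_{key}"] = 100.0 * count / n if n else float("nan")
    return summary
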