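"""Boltzmann ensemble of two-site CsrA-bound mRNA conformations.

A conformation is one ordered pair of non-overlapping candidate sites bound
by a single CsrA homodimer.  Its total binding free energy is

    dG_total = dG_site1 + dG_site2 + dG_cooperativity + ddG_unfold   (RT)

and the probability of the mRNA being bound in conformation alpha is the
Boltzmann weight exp(-beta * dG_total) normalized over all M conformations.
Downstream analyses use the top-K most favorable conformations (K = 15 by
default), with probabilities rescaled to sum to one over that subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .energy import (
    SITE_LENGTH,
    BindingSite,
    CooperativityParameters,
    cooperativity_energy,
    normalize_rna,
)
from .folding import FoldCache, FoldingEngine, unfold_energy

__all__ = ["Conformation", "Ensemble", "EnsembleParams", "enumerate_pairs", "build_ensemble", "ensemble_summary"]


@dataclass(frozen=True)
class Conformation:
    """One unique ordered site pair with its four energy terms (RT)."""

    site1: BindingSite  # upstream
    site2: BindingSite  # downstream
    d: int  # 5'-start to 5'-start distance, nt
    dG_coop: float
    ddG_unfold: float
    dG_total: float
    boltzmann_p: float = 0.0  # over the full ensemble
    scaled_p: float = 0.0  # renormalized over the selected top-K

    @property
    def n_high_affinity(self) -> int:
        return int(self.site1.is_high_affinity) + int(self.site2.is_high_affinity)

    def sort_key(self) -> tuple[float, int, int]:
        return (self.dG_total, self.site1.start, self.site2.start)


@dataclass
class EnsembleParams:
    top_k: int = 15
    beta: float = 1.0  # inverse-energy constant; energies already in RT
    coop: CooperativityParameters = field(default_factory=CooperativityParameters)


@dataclass
class Ensemble:
    record_id: str
    conformations: list[Conformation]  # all M, sorted by dG_total ascending
    top_k: list[Conformation]
    beta: float
    k_requested: int = 15

    @property
    def M(self) -> int:
        return len(self.conformations)


def enumerate_pairs(
    sites: list[BindingSite],
) -> list[tuple[BindingSite, BindingSite, int]]:
    """All unique ordered pairs of distinct, non-overlapping sites.

    A homodimer cannot occupy two overlapping 5-nt footprints, so pairs whose
    windows overlap (start-to-start distance < 5) are excluded.  Emits
    ``(upstream, downstream, d)`` with d the start-to-start distance.
    """
    ordered = sorted(sites, key=lambda s: s.start)
    if len(ordered) < 2:
        warnings.warn("fewer than two sites: no two-site conformation possible", stacklevel=2)
        return []
    pairs = []
    for i, s1 in enumerate(ordered):
        for s2 in ordered[i + 1 :]:
            d = s2.start - s1.start
            if d >= SITE_LENGTH:
                pairs.append((s1, s2, d))
    return pairs


def build_ensemble(
    seq: str,
    sites: list[BindingSite],
    engine: FoldingEngine | FoldCache,
    params: EnsembleParams | None = None,
    record_id: str = "",
) -> Ensemble:
    """Assemble the full conformational ensemble for one mRNA.

    All pairs are retained regardless of distance: pairs beyond the
    cooperative window get dG_coop = 0, sterically clashing pairs get the
    +20 RT penalty (they stay in M but essentially never reach the top-K).
    ddG_unfold is computed lazily with memoization on the constraint set.
    """
    params = params or EnsembleParams()
    s = normalize_rna(seq)
    if not isinstance(engine, FoldCache):
        engine = FoldCache(engine)
    confs: list[Conformation] = []
    for s1, s2, d in enumerate_pairs(sites):
        dg_coop = cooperativity_energy(d, params.coop)
        ddg = unfold_energy(s, s1, s2, engine)
        confs.append(
            Conformation(
                site1=s1,
                site2=s2,
                d=d,
                dG_coop=dg_coop,
                ddG_unfold=ddg,
                dG_total=s1.dG_site + s2.dG_site + dg_coop + ddg,
            )
        )
    if not confs:
        return Ensemble(
            record_id=record_id,
            conformations=[],
            top_k=[],
            beta=params.beta,
            k_requested=params.top_k,
        )

    energies = np.array([c.dG_total for c in confs])
    log_w = -params.beta * energies
    log_z = logsumexp(log_w)
    probs = np.exp(log_w - log_z)
    confs = [
        Conformation(
            site1=c.site1,
            site2=c.site2,
            d=c.d,
            dG_coop=c.dG_coop,
            ddG_unfold=c.ddG_unfold,
            dG_total=c.dG_total,
            boltzmann_p=float(p),
        )
        for c, p in zip(confs, probs)
    ]
    confs.sort(key=Conformation.sort_key)
    top = confs[: params.top_k]
    top_mass = sum(c.boltzmann_p for c in top)
    top = [
        Conformation(
            site1=c.site1,
            site2=c.site2,
            d=c.d,
            dG_coop=c.dG_coop,
            ddG_unfold=c.ddG_unfold,
            dG_total=c.dG_total,
            boltzmann_p=c.boltzmann_p,
            scaled_p=c.boltzmann_p / top_mass,
        )
        for c in top
    ]
    return Ensemble(
        record_id=record_id,
        conformations=confs,
        top_k=top,
        beta=params.beta,
        k_requested=params.top_k,
    )


def ensemble_summary(ens: Ensemble) -> dict:
    """Record-level metrics over the top-K conformations.

    Reports the most-likely conformation's dG_total, the unweighted and
    probability-weighted mean dG_total over the top-K, the scaled-probability
    fold-ratio between rank 1 and the last selected rank, and high-affinity
    site counts.  Flags ensembles with fewer than K conformations.
    """
    if not ens.top_k:
        raise ValueError("empty ensemble: no two-site conformation to summarize")
    top = ens.top_k
    energies = np.array([c.dG_total for c in top])
    weights = np.array([c.scaled_p for c in top])
    return {
        "record_id": ens.record_id,
        "M": ens.M,
        "k": len(top),
        "truncated": len(top) < ens.k_requested,
        "min_dG_total": float(energies[0]),
        "mean_dG_total_topk": float(energies.mean()),
        "weighted_mean_dG_total_topk": float((energies * weights).sum()),
        "rank1_to_rankK_prob_ratio": float(top[0].scaled_p / top[-1].scaled_p),
        "n_high_affinity_rank1": top[0].n_high_affinity,
        "n_high_affinity_per_conformation": [c.n_high_affinity for c in top],
    }
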