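"""Synthetic mRNA fixtures with known ground truth.

Each generator emits an :class:`~csramod.records.MRNARecord` built from a
low-complexity C/U background (which cannot contain favorable CsrA windows)
with planted features -- consensus and near-consensus sites at controlled
spacing, Shine-Dalgarno + start-codon scaffolds, and stems engineered to
sequester the ribosome footprint -- plus a ground-truth annotation of the
planted coordinates and the intended qualitative outcome.  Everything is
deterministic for a fixed seed.

Kinds
-----
``planted_pair``
    Two consensus AAGGA sites at a controlled spacing, far upstream of an
    otherwise unstructured SD + AUG scaffold; the pair dominates the
    ensemble and does not touch the ribosome footprint (expected: no impact).
``sd_occluder``
    Consensus site embedded in the Shine-Dalgarno region with an upstream
    partner (expected: repression).
``start_occluder``
    Consensus site overlapping the start codon (CDS begins AUGGA...) with an
    upstream partner (expected: repression).
``hairpin_sequestered_sd``
    SD sequestered by a planted antisense arm; no strong upstream sites.
    Used to compare free-state initiation energetics against the
    unstructured scaffold.
``activation_candidate``
    A long stem pairs the start-codon region of the CDS with an upstream arm
    carrying two consensus sites; CsrA binding melts the inhibitory stem
    (expected: activation).
``no_site_null``
    Pure C/U record: zero favorable windows, zero conformations.
``pocket_cluster``
    A tiled run of overlapping near-consensus (non-ANGGN) sites plus a
    downstream consensus partner; the cluster forms one flexible pocket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import MRNARecord

__all__ = ["FIXTURE_KINDS", "generate_fixture", "Fixture"]

SD = "AGGAGG"
SPACER = "CUCUC"  # 5 nt: optimal SD-to-start spacing by construction
AUG = "AUG"

FIXTURE_KINDS = (
    "planted_pair",
    "sd_occluder",
    "start_occluder",
    "hairpin_sequestered_sd",
    "activation_candidate",
    "no_site_null",
    "pocket_cluster",
)


@dataclass(frozen=True)
class Fixture:
    record: MRNARecord
    truth: dict


def _bg(phase: int, n: int) -> str:
    """Unstructured background: strictly alternating C/U.

    C/U-only sequence contains no favorable CsrA window, cannot base-pair
    with itself (C-U is not a pair), and the alternation leaves no CC/UU
    doublets, so planted G-rich elements find no stable pairing partner
    either -- the background is structurally inert by construction.  One
    phase (C-first or U-first) is drawn per record.
    """
    return "".join("CU"[(phase + i) % 2] for i in range(n))


def _record(name: str, seed: int, utr: str, cds: str) -> MRNARecord:
    return MRNARecord(id=f"{name}_s{seed}", sequence=utr + cds, cds_start=len(utr))


def _revcomp(s: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(s))


def generate_fixture(kind: str, seed: int = 0, **params) -> Fixture:
    """Generate one fixture record plus its ground-truth annotation."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    builder = globals()[f"_build_{kind}"]
    return builder(rng, seed, **params)


def _build_planted_pair(
    rng, seed, spacing: int = 15, upstream_gap: int = 25, pad: int = 10, cds_len: int = 60
) -> Fixture:
    phase = int(rng.integers(0, 2))
    utr = _bg(phase, pad) + "AAGGA" + _bg(phase, spacing - 5) + "AAGGA"
    site1, site2 = pad, pad + spacing
    utr += _bg(phase, upstream_gap) + SD + SPACER
    cds = AUG + _bg(phase, cds_len - 3)
    rec = _record("planted_pair", seed, utr, cds)
    return Fixture(
        rec,
        {
            "kind": "planted_pair",
            "planted_sites": [site1, site2],
            "spacing": spacing,
            "expected_top_pair": (site1, site2),
            "expected_regulation": "no_impact",
        },
    )


def _build_sd_occluder(rng, seed, partner_distance: int = 12, pad: int = 30, cds_len: int = 60) -> Fixture:
    # SD unit carries a consensus site: AAGGAGG; the AAGGA lands 12-7 nt
    # upstream of the start codon, inside the SD region and the footprint.
    phase = int(rng.integers(0, 2))
    sd_unit = "AAGGAGG"
    head = _bg(phase, pad) + "AAGGA" + _bg(phase, partner_distance - 5)
    partner = pad
    sd_site = len(head)
    utr = head + sd_unit + SPACER
    cds = AUG + _bg(phase, cds_len - 3)
    rec = _record("sd_occluder", seed, utr, cds)
    return Fixture(
        rec,
        {
            "kind": "sd_occluder",
            "planted_sites": [partner, sd_site],
            "expected_top_pair": (partner, sd_site),
            "expected_regulation": "repressed",
        },
    )


def _build_start_occluder(rng, seed, partner_distance: int = 20, pad: int = 30, cds_len: int = 60) -> Fixture:
    # CDS begins AUGGA: an ANGGN site sits directly on the start codon.
    # No SD element: initiation is driven by the start-codon term.
    phase = int(rng.integers(0, 2))
    utr = _bg(phase, pad) + "AAGGA" + _bg(phase, partner_distance - 5)
    partner = pad
    start_site = len(utr)
    cds = "AUGGA" + _bg(phase, cds_len - 5)
    rec = _record("start_occluder", seed, utr, cds)
    return Fixture(
        rec,
        {
            "kind": "start_occluder",
            "planted_sites": [partner, start_site],
            "expected_top_pair": (partner, start_site),
            "expected_regulation": "repressed",
        },
    )


def _build_hairpin_sequestered_sd(rng, seed, loop: int = 6, pad: int = 25, cds_len: int = 60) -> Fixture:
    # An antisense arm (revcomp of the SD+spacer head) sequesters the SD in
    # a stem; the arm itself is C/U-rich and contributes no strong sites.
    phase = int(rng.integers(0, 2))
    stem_target = SD + "U"
    arm = _revcomp(stem_target)  # ACCUCCU
    utr = _bg(phase, pad) + arm + _bg(phase, loop) + stem_target + SPACER[1:]
    arm_start = pad
    cds = AUG + _bg(phase, cds_len - 3)
    rec = _record("hairpin_sd", seed, utr, cds)
    return Fixture(
        rec,
        {
            "kind": "hairpin_sequestered_sd",
            "arm": (arm_start, arm_start + len(arm)),
            "sd_start": arm_start + len(arm) + loop,
            "expected_regulation": None,  # used for free-state energetics only
        },
    )


def _build_activation_candidate(rng, seed, pad: int = 10, cds_len: int = 60) -> Fixture:
    # A moderate 6-bp stem pairs a G-clamped consensus site (upstream, just
    # outside the footprint) with a UCCUUC target planted in the early CDS
    # (inside the footprint).  The free mRNA therefore carries an
    # inhibitory structure over the start region; the most favorable CsrA
    # pair binds the stem-arm site plus a far-upstream partner, melting the
    # stem and liberating the footprint.  The stem is deliberately weak
    # (~6 RT) so the melting cost does not price the activating pair out
    # of the top-K.
    phase = int(rng.integers(0, 2))
    utr = _bg(phase, pad) + "AAGGA" + _bg(phase, 6) + "GAAGGA" + _bg(phase, 20)
    site1, site2 = pad, pad + 12  # AAGGA of the stem arm starts one past the G clamp
    cds = "AUG" + _bg(phase, 3) + _revcomp("GAAGGA") + _bg(phase, cds_len - 12)
    rec = _record("activation", seed, utr, cds)
    return Fixture(
        rec,
        {
            "kind": "activation_candidate",
            "planted_sites": [site1, site2],
            "expected_top_pair": (site1, site2),
            "expected_regulation": "activated",
        },
    )


def _build_no_site_null(rng, seed, utr_len: int = 60, cds_len: int = 40) -> Fixture:
    phase = int(rng.integers(0, 2))
    rec = _record("null", seed, _bg(phase, utr_len), _bg(phase, cds_len))
    return Fixture(
        rec,
        {
            "kind": "no_site_null",
            "planted_sites": [],
            "expected_n_sites": 0,
            "expected_regulation": "not_assessable",
        },
    )


def _build_pocket_cluster(
    rng, seed, n_repeats: int = 3, partner_gap: int = 20, pad: int = 10, cds_len: int = 40
) -> Fixture:
    # "AAG" tiling yields overlapping near-consensus windows (AAGAA, GAAGA,
    # AGAAG), none matching ANGGN; a downstream consensus AAGGA partner
    # pairs with each of them at cooperative distances.
    phase = int(rng.integers(0, 2))
    cluster = "AAG" * n_repeats
    cluster_start = pad
    utr = _bg(phase, pad) + cluster + _bg(phase, partner_gap) + "AAGGA" + _bg(phase, 15)
    partner = pad + len(cluster) + partner_gap
    cds = AUG + _bg(phase, cds_len - 3)
    rec = _record("pocket_cluster", seed, utr, cds)
    return Fixture(
        rec,
        {
            "kind": "pocket_cluster",
            "cluster_span": (cluster_start, cluster_start + len(cluster)),
            "partner_site": partner,
            "expected_flexible_pocket": True,
        },
    )
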