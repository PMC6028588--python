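"""Sequence free-energy model for CsrA binding sites.

CsrA (carbon storage regulator A) is a homodimeric RNA-binding protein that
recognizes short ANGGA-like elements in mRNA 5' regions.  This module scores
5-nt windows with a position-specific mono-nucleotide free-energy matrix
(entries in RT units, derived from EMSA binding affinities of single-mutant
consensus sites), enumerates candidate binding sites, evaluates the
distance-dependent cooperativity energy of a homodimer bridging two sites,
and provides the two classical sequence-search baselines for comparison.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RT_KCAL",
    "BASES",
    "FreeEnergyMatrix",
    "BindingSite",
    "CooperativityParameters",
    "normalize_rna",
    "score_window",
    "scan_sites",
    "is_high_affinity",
    "cooperativity_energy",
    "baseline_mckee",
    "baseline_kulkarni",
    "KulkarniResult",
]

#: RT at 37 degC in kcal/mol (R = 1.9872e-3 kcal/mol/K, T = 310.15 K).
#: All model energies are carried in RT units; multiply by this to get kcal/mol.
RT_KCAL = 0.61633

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default per-position free-energy contributions (RT).  Rows are positions
#: 1-5 of the site, columns A, C, G, U.  Favorable (negative) entries reward
#: the consensus AAGGA; every other entry is zero.
_DEFAULT_ENTRIES = np.array(
    [
        [-2.63, 0.0, 0.0, 0.0],
        [-2.20, 0.0, 0.0, 0.0],
        [0.0, 0.0, -3.14, 0.0],
        [0.0, 0.0, -3.14, 0.0],
        [-1.65, 0.0, 0.0, 0.0],
    ]
)

SITE_LENGTH = 5


class SequenceAlphabetError(ValueError):
    """Raised when an input sequence contains a non-ACGU/T character."""


def normalize_rna(seq: str) -> str:
    """Uppercase *seq*, map T->U, and validate the alphabet.

    IUPAC ambiguity codes (and anything else outside ACGUT) are rejected with
    a diagnostic naming the first offending position and character.
    """
    s = seq.upper().replace("T", "U")
    for pos, ch in enumerate(s):
        if ch not in _BASE_INDEX:
            raise SequenceAlphabetError(
                f"invalid character {ch!r} at position {pos}: expected A/C/G/U (or T)"
            )
    return s


@dataclass(frozen=True)
class FreeEnergyMatrix:
    """Position-specific mono-nucleotide free-energy matrix (5 x ACGU, RT)."""

    entries: np.ndarray = field(default_factory=lambda: _DEFAULT_ENTRIES.copy())

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (SITE_LENGTH, 4):
            raise ValueError(f"matrix must be {SITE_LENGTH}x4 (A,C,G,U), got {e.shape}")
        if (e > 0).any():
            raise ValueError("all matrix entries must be <= 0 (favorable or neutral)")
        object.__setattr__(self, "entries", e)

    @property
    def consensus_energy(self) -> float:
        """Sum of the most favorable entry at each position (the lower bound)."""
        return float(self.entries.min(axis=1).sum())

    def lookup(self, position: int, base: str) -> float:
        return float(self.entries[position, _BASE_INDEX[base]])


def score_window(seq5: str, matrix: FreeEnergyMatrix | None = None) -> float:
    """Binding free energy (RT) of CsrA to a 5-nt site: sum of matrix entries.

    Returns 0 for a window with no favorable nucleotide at any position.
    """
    matrix = matrix or FreeEnergyMatrix()
    s = normalize_rna(seq5)
    if len(s) != SITE_LENGTH:
        raise ValueError(f"site must be {SITE_LENGTH} nt, got {len(s)}")
    return float(sum(matrix.entries[i, _BASE_INDEX[b]] for i, b in enumerate(s)))


def is_high_affinity(seq5: str) -> bool:
    """True iff the 5-mer matches the ANGGN consensus pattern."""
    s = normalize_rna(seq5)
    return len(s) == SITE_LENGTH and s[0] == "A" and s[2] == "G" and s[3] == "G"


@dataclass(frozen=True, order=True)
class BindingSite:
    """A candidate 5-nt CsrA binding site.

    ``start`` is a 0-based offset into the analyzed sequence; ``dG_site`` is
    the matrix score in RT (strictly negative for retained sites);
    ``is_high_affinity`` marks ANGGN consensus matches.
    """

    start: int
    sequence: str
    dG_site: float
    is_high_affinity: bool

    @property
    def end(self) -> int:
        """Half-open end coordinate."""
        return self.start + SITE_LENGTH


def scan_sites(seq: str, matrix: FreeEnergyMatrix | None = None) -> list[BindingSite]:
    """Identify candidate CsrA sites: every 5-nt window with score < 0.

    Windows scoring exactly 0 (no favorable nucleotide) are excluded.  The
    result is sorted by start coordinate.  A sequence shorter than 5 nt
    yields an empty list with a warning.
    """
    matrix = matrix or FreeEnergyMatrix()
    s = normalize_rna(seq)
    if len(s) < SITE_LENGTH:
        warnings.warn(
            f"sequence of length {len(s)} is shorter than one {SITE_LENGTH}-nt site; "
            "no sites scanned",
            stacklevel=2,
        )
        return []
    # vectorized lookup: one-hot-free indexing of the matrix per offset
    idx = np.array([_BASE_INDEX[b] for b in s])
    n_win = len(s) - SITE_LENGTH + 1
    scores = np.zeros(n_win)
    for i in range(SITE_LENGTH):
        scores += matrix.entries[i, idx[i : i + n_win]]
    sites = []
    for start in np.nonzero(scores < 0)[0]:
        sub = s[start : start + SITE_LENGTH]
        sites.append(
            BindingSite(
                start=int(start),
                sequence=sub,
                dG_site=float(scores[start]),
                is_high_affinity=is_high_affinity(sub),
            )
        )
    return sites


@dataclass(frozen=True)
class CooperativityParameters:
    """Distance-dependent cooperativity of a CsrA homodimer bridging two sites.

    For inter-site distances d (5'-start to 5'-start, nt) in the cooperative
    window the energy is the quadratic a*(d-offset)^2 + b*(d-offset) + c (RT);
    below the window the dimer footprints sterically clash (+20 RT); above it
    the second RNA-binding surface cannot reach, so the contribution is zero.
    """

    a: float = 0.001
    b: float = 0.05
    c: float = -5.0
    offset: int = 5
    d_min: int = 10
    d_max: int = 55
    steric_penalty: float = 20.0


def cooperativity_energy(
    d: int, params: CooperativityParameters | None = None
) -> float:
    """Cooperativity free energy (RT) for two sites *d* nt apart (start-to-start)."""
    params = params or CooperativityParameters()
    if d <= 0:
        raise ValueError(f"inter-site distance must be positive, got {d}")
    if d < params.d_min:
        return params.steric_penalty
    if d > params.d_max:
        return 0.0
    x = d - params.offset
    return params.a * x * x + params.b * x + params.c


# --- published sequence-search baselines ------------------------------------

#: Degenerate 8-mer motif of the McKee et al. genome scan.
MCKEE_MOTIF = re.compile(r"(?=([ACU]A[AGU]GGA[AGU][ACU]))")
MCKEE_WINDOW = 22


def baseline_mckee(seq: str, cds_start: int) -> list[tuple[int, str]]:
    """Matches of the degenerate [A/C/U]A[A/G/U]GGA[A/G/U][A/C/U] motif
    wholly inside the 22-nt window immediately upstream of the start codon.

    Returns ``(start, matched_8mer)`` tuples in sequence coordinates.
    """
    s = normalize_rna(seq)
    if cds_start < 0 or cds_start > len(s):
        raise ValueError(f"cds_start {cds_start} outside sequence of length {len(s)}")
    lo = max(0, cds_start - MCKEE_WINDOW)
    window = s[lo:cds_start]
    return [(lo + m.start(1), m.group(1)) for m in MCKEE_MOTIF.finditer(window)]


_ANGGA = re.compile(r"(?=(A[ACGU]?GGA))")  # AGGA or ANGGA (N = one nucleotide)
_GGA = re.compile(r"(?=(GGA))")


def _angga_elements(region: str) -> list[tuple[int, str]]:
    """Non-overlapping A(N)GGA elements, greedy leftmost-longest.

    A nested AGGA inside an already-counted ANGGA is the same element, not a
    second one.
    """
    hits = []
    pos = 0
    while pos <= len(region) - 4:
        if region.startswith("A", pos):
            for length in (5, 4):
                chunk = region[pos : pos + length]
                if len(chunk) == length and chunk[0] == "A" and chunk[-3:] == "GGA":
                    hits.append((pos, chunk))
                    pos += length
                    break
            else:
                pos += 1
        else:
            pos += 1
    return hits


@dataclass(frozen=True)
class KulkarniResult:
    passes: bool
    matches: list[tuple[int, str]]  # A(N)GGA matches in the -30..+5 window
    rule_three_sites: bool
    rule_two_plus_gga: bool


def baseline_kulkarni(
    seq: str, cds_start: int, gga_pattern: str | re.Pattern = _GGA
) -> KulkarniResult:
    """Sequence-search baseline requiring multiple clustered A(N)GGA elements.

    The gene passes if, within the region from the record start to 30 nt of
    coding sequence, either (a) at least three A(N)GGA elements occur with
    consecutive spacings of 10-60 nt, or (b) two A(N)GGA elements each have a
    separate GGA-like trinucleotide within 10 nt.  Reported ``matches`` are
    restricted to the window 30 nt upstream to 5 nt downstream of the start
    codon.  The "GGA-like" degeneracy is a plain GGA by default (configurable
    via *gga_pattern*).
    """
    if isinstance(gga_pattern, str):
        gga_pattern = re.compile(f"(?=({gga_pattern}))")
    s = normalize_rna(seq)
    if cds_start < 0 or cds_start > len(s):
        raise ValueError(f"cds_start {cds_start} outside sequence of length {len(s)}")
    region = s[: min(len(s), cds_start + 30)]
    hits = _angga_elements(region)

    # rule (a): >= 3 elements forming a chain with consecutive spacings 10-60 nt
    starts = [h[0] for h in hits]
    rule_a = False
    for i in range(len(starts)):
        chain = 1
        prev = starts[i]
        for j in range(i + 1, len(starts)):
            gap = starts[j] - prev
            if 10 <= gap <= 60:
                chain += 1
                prev = starts[j]
                if chain >= 3:
                    rule_a = True
                    break
        if rule_a:
            break

    # rule (b): >= 2 elements each with a disjoint GGA within 10 nt
    gga_hits = [m.start(1) for m in gga_pattern.finditer(region)]
    n_supported = 0
    for start, motif in hits:
        span = (start, start + len(motif))
        for g in gga_hits:
            if g + 3 <= span[0] or g >= span[1]:  # disjoint occurrences only
                if abs(g - start) <= 10:
                    n_supported += 1
                    break
    rule_b = n_supported >= 2

    lo, hi = max(0, cds_start - 30), min(len(s), cds_start + 5)
    window_matches = [(p, m) for p, m in hits if lo <= p < hi]
    return KulkarniResult(
        passes=rule_a or rule_b,
        matches=window_matches,
        rule_three_sites=rule_a,
        rule_two_plus_gga=rule_b,
    )
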