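"""RNA secondary-structure folding with single-strandedness constraints.

The structural term of the binding model asks: how much folding free energy
must be sacrificed to hold both CsrA footprints single-stranded?  That is the
difference between the minimum-free-energy (MFE) fold computed under a
forced-unpaired constraint on the site positions and the unconstrained MFE
fold.  Constrained positions may not base-pair but may sit anywhere in the
structure, including inside hairpin loops.

Folding is delegated to ViennaRNA through an injectable engine object so the
thermodynamic rule set, temperature, and dangling-end treatment are pinned
and echoed into every result.  Defaults follow the model's calibration:
Turner 1999 parameters, 37 degC, dangling-end energies disabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol

from .energy import RT_KCAL, BindingSite, normalize_rna

__all__ = ["FoldResult", "FoldingEngine", "ViennaEngine", "FoldCache", "unfold_energy"]


class EngineConfigurationError(RuntimeError):
    """Raised when no usable folding engine is configured/available."""


@dataclass(frozen=True)
class FoldResult:
    """An MFE structure prediction.

    ``free_energy`` is in RT units (converted from the engine's kcal/mol);
    ``structure`` is the dot-bracket string; ``constrained`` records whether
    forced-unpaired positions were applied.
    """

    structure: str
    free_energy: float
    constrained: bool
    engine_info: str = ""


class FoldingEngine(Protocol):
    """Structure-prediction provider contract used throughout the package."""

    def fold(self, seq: str, forced_unpaired: Iterable[int] = ()) -> FoldResult:
        """MFE fold of *seq*; positions in *forced_unpaired* (0-based) may not pair."""
        ...

    @property
    def identifier(self) -> str:
        """Human-readable engine + rule-set description for provenance."""
        ...


class ViennaEngine:
    """ViennaRNA MFE folding adapter.

    Parameters
    ----------
    temperature : folding temperature in degC (default 37).
    dangles : ViennaRNA dangling-end mode; 0 disables dangling-nucleotide
        energies, matching the model's calibration.
    parameters : thermodynamic rule set, ``"turner1999"`` or ``"turner2004"``.
    no_lonely_pairs : forbid isolated base pairs (engine default: allowed).
    """

    def __init__(
        self,
        temperature: float = 37.0,
        dangles: int = 0,
        parameters: str = "turner1999",
        no_lonely_pairs: bool = False,
    ) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - environment guard
            raise EngineConfigurationError(
                "ViennaRNA Python bindings not importable; install the "
                "'ViennaRNA' package or supply another FoldingEngine"
            ) from exc
        self._RNA = RNA
        self.temperature = float(temperature)
        self.dangles = int(dangles)
        self.parameters = parameters
        self.no_lonely_pairs = bool(no_lonely_pairs)
        if parameters == "turner1999":
            RNA.params_load_RNA_Turner1999()
        elif parameters == "turner2004":
            RNA.params_load_RNA_Turner2004()
        else:
            raise EngineConfigurationError(
                f"unknown parameter set {parameters!r}; expected 'turner1999' or 'turner2004'"
            )
        # global settings consumed by duplexfold (used by the translation model)
        RNA.cvar.dangles = self.dangles
        RNA.cvar.temperature = self.temperature
        self._md = RNA.md()
        self._md.temperature = self.temperature
        self._md.dangles = self.dangles
        self._md.noLP = 1 if no_lonely_pairs else 0

    @property
    def identifier(self) -> str:
        return (
            f"ViennaRNA {self._RNA.__version__} ({self.parameters}, "
            f"T={self.temperature:g}C, dangles={self.dangles}, "
            f"noLP={int(self.no_lonely_pairs)})"
        )

    def fold(self, seq: str, forced_unpaired: Iterable[int] = ()) -> FoldResult:
        s = normalize_rna(seq)
        positions = sorted(set(forced_unpaired))
        if positions and (positions[0] < 0 or positions[-1] >= len(s)):
            raise ValueError(
                f"forced-unpaired positions {positions[0]}..{positions[-1]} outside "
                f"sequence of length {len(s)}"
            )
        fc = self._RNA.fold_compound(s, self._md)
        for p in positions:
            fc.hc_add_up(p + 1)  # ViennaRNA constraint API is 1-based
        structure, mfe_kcal = fc.mfe()
        return FoldResult(
            structure=structure,
            free_energy=mfe_kcal / RT_KCAL,
            constrained=bool(positions),
            engine_info=self.identifier,
        )

    def duplex_energy(self, seq1: str, seq2: str):
        """Best inter-molecular duplex between two strands (RNA.duplexfold).

        Returns ``(energy_RT, last_paired_pos_seq1)`` where the position is the
        0-based index of the 3'-most paired nucleotide of *seq1*, or
        ``(0.0, None)`` when no favorable duplex exists.  Used by the
        translation model for SD:anti-SD hybridization.
        """
        d = self._RNA.duplexfold(normalize_rna(seq1), normalize_rna(seq2))
        if d.energy >= 0 or "(" not in d.structure:
            return 0.0, None
        part1 = d.structure.split("&")[0]
        trailing_dots = len(part1) - len(part1.rstrip("."))
        last_paired = d.i - trailing_dots - 1  # d.i: 1-based end of region in seq1
        return d.energy / RT_KCAL, last_paired


class FoldCache:
    """Memoizes fold results per (sequence, constraint-set).

    Many site pairs share footprints, and the translation model re-folds the
    same sequence under overlapping constraint sets; caching makes ensemble
    construction roughly linear in the number of *distinct* constraint sets.
    """

    def __init__(self, engine: FoldingEngine) -> None:
        self.engine = engine
        self._cache: dict[tuple[str, frozenset[int]], FoldResult] = {}

    def fold(self, seq: str, forced_unpaired: Iterable[int] = ()) -> FoldResult:
        key = (seq, frozenset(forced_unpaired))
        if key not in self._cache:
            self._cache[key] = self.engine.fold(seq, key[1])
        return self._cache[key]

    @property
    def identifier(self) -> str:
        return self.engine.identifier


def site_positions(*sites: BindingSite) -> frozenset[int]:
    """Union of the nucleotide positions covered by the given sites."""
    pos: set[int] = set()
    for s in sites:
        pos.update(range(s.start, s.end))
    return frozenset(pos)


def unfold_energy(
    seq: str,
    site1: BindingSite,
    site2: BindingSite,
    engine: FoldingEngine | FoldCache,
) -> float:
    """Structural-change penalty ddG_unfold (RT) for a pair of sites.

    Constrained-MFE energy (both 5-nt footprints forced single-stranded)
    minus the unconstrained MFE energy.  Non-negative by construction;
    exactly 0 when both sites are already unpaired in the MFE structure.
    Overlapping sites are merged into one constraint set.
    """
    s = normalize_rna(seq)
    for site in (site1, site2):
        if site.end > len(s) or site.start < 0:
            raise ValueError(
                f"site [{site.start},{site.end}) outside sequence of length {len(s)}"
            )
    unconstrained = engine.fold(s)
    constrained = engine.fold(s, site_positions(site1, site2))
    ddg = constrained.free_energy - unconstrained.free_energy
    # guard against engine round-off producing tiny negative differences
    return max(ddg, 0.0)
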