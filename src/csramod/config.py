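"""Model configuration: every tunable constant, serialized for provenance.

Each output file embeds the configuration (and its hash) plus the folding
engine's identifier so a result can always be traced back to the exact
parameterization that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .energy import CooperativityParameters, FreeEnergyMatrix
from .ensemble import EnsembleParams
from .titration import LEAKINESS
from .translation import TranslationParams

__all__ = ["ModelConfig"]


@dataclass
class ModelConfig:
    """Aggregated model parameters with JSON serialization and hashing."""

    matrix: FreeEnergyMatrix = field(default_factory=FreeEnergyMatrix)
    coop: CooperativityParameters = field(default_factory=CooperativityParameters)
    top_k: int = 15
    beta: float = 1.0
    translation: TranslationParams = field(default_factory=TranslationParams)
    strong_coop_energy: float = -4.0
    strong_coop_max_d: int = 25
    large_structure_change: float = 3.0
    pocket_gap: int = 1
    flexible_low: int = 7
    flexible_high: int = 10
    leakiness: float = LEAKINESS
    engine_temperature: float = 37.0
    engine_dangles: int = 0
    engine_parameters: str = "turner1999"
    seed: int = 0

    def ensemble_params(self) -> EnsembleParams:
        return EnsembleParams(top_k=self.top_k, beta=self.beta, coop=self.coop)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if hasattr(obj, "tolist"):
                return obj.tolist()
            if isinstance(obj, dict):
                return {str(k): convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj

        out = {}
        for f in dataclasses.fields(self):
            out[f.name] = convert(getattr(self, f.name))
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
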