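"""Run configuration: one YAML file with model/cohort/game/analysis blocks.

A master seed deterministically derives every stage seed, so a run is
reproducible end to end from the config alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortConfig, SequenceMatrix
from .model_core import ModelParams
from .simulator import GameConfig

__all__ = ["RunConfig", "load_config", "load_sequence_matrix", "stage_seed"]

# Fixed offsets so each pipeline stage gets an independent, reproducible
# substream of the master seed.
_STAGE_OFFSETS = {"cohort": 1, "simulate": 2, "analysis": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    import numpy as np

    ss = np.random.SeedSequence([master_seed, _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All knobs of a full pipeline run."""

    model: ModelParams = field(default_factory=ModelParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    game: GameConfig = field(default_factory=GameConfig)
    specs: tuple = ("group_round", "group_session", "individual_round",
                    "individual_session")
    include_controls: bool = False
    seed: int = 0
    outdir: str = "boswellia_run"

    def __post_init__(self) -> None:
        # The master seed overrides the stage seeds of the sub-configs.
        self.cohort.seed = stage_seed(self.seed, "cohort")
        self.game.seed = stage_seed(self.seed, "simulate")
        self.game.model = self.model

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "model": self.model.to_dict(),
            "cohort": dataclasses.asdict(self.cohort),
            "game": {
                k: v for k, v in dataclasses.asdict(self.game).items()
                if k != "model"
            },
            "analysis": {
                "specs": list(self.specs),
                "include_controls": self.include_controls,
            },
        }


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file (or defaults when path is None)."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    model = ModelParams(**raw.get("model", {}))
    cohort = CohortConfig(**raw.get("cohort", {}))
    game_kwargs = dict(raw.get("game", {}))
    game_kwargs.pop("model", None)
    game = GameConfig(model=model, **game_kwargs)
    analysis = raw.get("analysis", {})
    cfg = RunConfig(
        model=model,
        cohort=cohort,
        game=game,
        specs=tuple(analysis.get("specs", RunConfig.specs)),
        include_controls=bool(analysis.get("include_controls", False)),
        seed=int(raw.get("seed", 0) if seed is None else seed),
        outdir=str(raw.get("outdir", "boswellia_run")),
    )
    return cfg


def load_sequence_matrix(path: str | Path | None = None) -> SequenceMatrix:
    """Sequence matrix from a JSON file, or the packaged default.

    The JSON layout is ``{"sequences": [[scenario x 6], ...]}``.
    """
    if path is None:
        from importlib import resources

        raw = resources.files("boswellia.data").joinpath("sequences.json").read_text()
    else:
        raw = Path(path).read_text()
    rows = json.loads(raw)["sequences"]
    return SequenceMatrix(tuple(tuple(r) for r in rows))
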