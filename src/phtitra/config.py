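"""Run configuration: structured-text (YAML) parsing and validation.

A :class:`RunConfig` bundles everything a full pipeline run needs — state
cut-offs, H-bond criteria, graph specifications, the reference pKa table,
frame selection and seeds — and validates the graph (set, angle, threshold)
triples against the canonical mapping and the cut-off ordering before any
stage executes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hbond import GraphSpec, GraphSet, HBondCriteria
from .titration import ReferencePKaTable, StateCutoffs

__all__ = ["FrameSelection", "RunConfig"]


@dataclass(frozen=True)
class FrameSelection:
    """first/last/stride frame subsampling applied before analysis."""

    start: int | None = None
    stop: int | None = None
    stride: int | None = None

    def as_slice(self) -> slice:
        return slice(self.start, self.stop, self.stride)


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    cutoffs: StateCutoffs = field(default_factory=StateCutoffs)
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    graph_specs: tuple[GraphSpec, ...] = (
        GraphSpec(GraphSet.BACKBONE_SIDECHAIN_WATER, 60),
        GraphSpec(GraphSet.SIDECHAIN_WATER, 60),
        GraphSpec(GraphSet.SIDECHAIN_DIRECT, 60),
    )
    reference_pka: ReferencePKaTable = field(default_factory=ReferencePKaTable.default)
    frame_selection: FrameSelection = field(default_factory=FrameSelection)
    seed: int = 0
    output_dir: Path = Path("phtitra_out")
    titration_dir: Path | None = None  # directory of λ-record TSV files
    trajectory: Path | None = None  # multi-model PDB for hbond/conf stages
    synthetic: dict | None = None  # inline synthetic demo parameters

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "cutoffs" in raw:
            kwargs["cutoffs"] = StateCutoffs(**raw["cutoffs"])
        if "criteria" in raw:
            kwargs["criteria"] = HBondCriteria(**raw["criteria"])
        if "graph_specs" in raw:
            kwargs["graph_specs"] = tuple(
                GraphSpec(
                    graph_set=GraphSet(int(g["graph_set"])),
                    angle_criterion=int(g["angle_criterion"]),
                    occupancy_threshold=g.get("occupancy_threshold"),
                    allow_override=bool(g.get("allow_override", False)),
                )
                for g in raw["graph_specs"]
            )
        if "reference_pka" in raw:
            ref = raw["reference_pka"]
            if isinstance(ref, str):
                kwargs["reference_pka"] = ReferencePKaTable.from_yaml(
                    Path(path).parent / ref
                )
            else:
                kwargs["reference_pka"] = ReferencePKaTable(
                    values={str(k).upper(): float(v) for k, v in ref.items()}
                )
        if "frame_selection" in raw:
            kwargs["frame_selection"] = FrameSelection(**raw["frame_selection"])
        for key in ("seed",):
            if key in raw:
                kwargs[key] = int(raw[key])
        for key in ("output_dir", "titration_dir", "trajectory"):
            if key in raw and raw[key] is not None:
                kwargs[key] = Path(raw[key])
        if "synthetic" in raw:
            kwargs["synthetic"] = raw["synthetic"]
        return cls(**kwargs)
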