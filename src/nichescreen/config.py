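"""Pipeline configuration: defaults, YAML/TOML loading, validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import PlantedCircuit, SimConfig


class ConfigError(ValueError):
    """Configuration file or values are invalid."""


@dataclass
class PipelineConfig:
    """End-to-end run parameters.

    The defaults mirror the screen's published operating point: a 5 RPKM
    expression threshold, highly-variable-gene selection at alpha 0.01 after
    Benjamini-Hochberg, a 0.05 nominal-p cutoff for the enrichment graph,
    and a 20-bin 0-15 log2(RPKM + 1) overlay window.
    """

    expression_threshold: float = 5.0
    hvg_alpha: float = 0.01
    gsea_p_cutoff: float = 0.05
    n_bins: int = 20
    overlay_range: tuple[float, float] = (0.0, 15.0)
    pseudocount: float = 1.0
    nperm: int = 1000
    min_confidence: float = 0.0
    similarity_cutoff: float = 0.5
    gsea_weight: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    comparison: tuple[str, str] = ("EPI", "TE")
    seed: int = 0
    out_dir: str = "results"
    # optional external inputs; simulation is used when matrix_path is None
    matrix_path: str | None = None
    annotations_path: str | None = None
    gene_lengths_path: str | None = None
    catalogue_path: str | None = None
    ppi_path: str | None = None
    genesets_path: str | None = None
    pathway_path: str | None = None
    simulation: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> list[str]:
        """Return a diagnostic per violated field (empty when valid)."""
        diagnostics = []
        if self.expression_threshold < 0:
            diagnostics.append("expression_threshold: must be >= 0 RPKM")
        for name in ("hvg_alpha", "gsea_p_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                diagnostics.append(f"{name}: must lie in (0, 1)")
        if self.n_bins < 2:
            diagnostics.append("n_bins: must be >= 2")
        if len(self.overlay_range) != 2 or self.overlay_range[1] <= self.overlay_range[0]:
            diagnostics.append("overlay_range: must be an increasing (low, high) pair")
        if self.pseudocount <= 0:
            diagnostics.append("pseudocount: must be positive")
        if self.nperm < 1:
            diagnostics.append("nperm: must be >= 1")
        if not 0 <= self.min_confidence <= 1:
            diagnostics.append("min_confidence: must lie in [0, 1]")
        if not 0 <= self.similarity_cutoff <= 1:
            diagnostics.append("similarity_cutoff: must lie in [0, 1]")
        if len(self.comparison) != 2 or self.comparison[0] == self.comparison[1]:
            diagnostics.append("comparison: needs two distinct lineage names")
        try:
            self.simulation.validate()
        except ValueError as exc:
            diagnostics.append(f"simulation: {exc}")
        return diagnostics


def _build_sim_config(payload: dict) -> SimConfig:
    allowed = {f.name for f in fields(SimConfig)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigError(f"unknown simulation key(s): {sorted(unknown)}")
    if "planted_pairs" in payload:
        payload["planted_pairs"] = [
            PlantedCircuit(**p) if isinstance(p, dict) else p
            for p in payload["planted_pairs"]
        ]
    if "planted_gene_sets" in payload:
        payload["planted_gene_sets"] = [tuple(s) for s in payload["planted_gene_sets"]]
    if "cells_per_lineage" in payload:
        payload["cells_per_lineage"] = dict(payload["cells_per_lineage"])
    if "length_range" in payload:
        payload["length_range"] = tuple(payload["length_range"])
    return SimConfig(**payload)


def load_config(path) -> PipelineConfig:
    """Load a YAML (or TOML) config; absent keys fall back to defaults,
    unknown keys are rejected by name."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        payload = tomllib.loads(path.read_text())
    else:
        payload = yaml.safe_load(path.read_text())
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigError("config file must contain a mapping")
    allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "simulation" in payload and isinstance(payload["simulation"], dict):
        payload["simulation"] = _build_sim_config(dict(payload["simulation"]))
    for key in ("overlay_range", "comparison"):
        if key in payload:
            payload[key] = tuple(payload[key])
    config = PipelineConfig(**payload)
    diagnostics = config.validate()
    if diagnostics:
        raise ConfigError("invalid configuration: " + "; ".join(diagnostics))
    return config


def save_config(config: PipelineConfig, path) -> None:
    payload = dataclasses.asdict(config)
    payload["overlay_range"] = list(config.overlay_range)
    payload["comparison"] = list(config.comparison)
    payload["simulation"]["cells_per_lineage"] = dict(config.simulation.cells_per_lineage)
    payload["simulation"]["length_range"] = list(config.simulation.length_range)
    payload["simulation"]["planted_pairs"] = [
        dataclasses.asdict(p) for p in config.simulation.planted_pairs
    ]
    payload["simulation"]["planted_gene_sets"] = [
        list(s) for s in config.simulation.planted_gene_sets
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
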