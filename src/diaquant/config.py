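"""Resolved pipeline configuration: one dataclass, YAML/JSON round-trip.

The snapshot written next to every report reproduces the run when fed
back as config (fixed seeds, no wall-clock content).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # ingest
    column_map: dict[str, str] = field(default_factory=dict)
    # preprocess
    max_precursor_q: float = 0.01
    max_pg_q: float = 0.01
    remove_oxidized: bool = True
    oxidation_tags: list[str] = field(
        default_factory=lambda: ["M[Oxidation", "Oxidation (M)", "M(ox)", "M[+16]"]
    )
    min_fraction: float = 0.5
    normalize: bool = True
    adjust_batch: bool = True
    # quantification
    methods: list[str] = field(default_factory=lambda: ["iBAQ", "Hi3", "MaxLFQ"])
    digest_min_len: int = 7
    digest_max_len: int = 30
    missed_cleavages: int = 0
    min_peptides_pair: int = 2
    # statistics
    stat_method: str = "ropeca"  # ropeca | modt | t
    welch: bool = False
    alpha: float = 0.05
    # reporting
    log2fc_color_bound: float = 2.0
    report_title: str = "DIA-MS quantification report"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=1, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))
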