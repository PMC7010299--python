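"""Pipeline parameter block: one place for every tunable threshold."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml


@dataclass
class PipelineParams:
    """All pipeline thresholds with their defaults.

    The read-joining quality floor (30) and minimum merged length (25),
    the alignment e-value ceiling (1e-5) and the MAPQ floor (20) follow
    the published analysis settings; the remainder are declared package
    defaults, documented in the methods note.
    """

    qual_floor: int = 30
    min_merged_len: int = 25
    min_overlap: int = 10
    max_mismatch_rate: float = 0.1
    evalue_max: float = 1e-5
    min_word: int = 11
    min_identity: float = 0.85
    max_read_gap: int = 10
    max_read_overlap: int = 10
    min_ltr_overlap: int = 20
    junction_tolerance: int = 0
    flank: int = 177
    min_overhang: int = 10
    max_residual: int = 1
    mapq_min: int = 20
    pseudocount: float = 1.0
    efficiency: float = 2.0
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.qual_floor >= 0, "qual_floor must be >= 0"),
            (self.min_merged_len >= 1, "min_merged_len must be >= 1"),
            (self.min_overlap >= 1, "min_overlap must be >= 1"),
            (0 <= self.max_mismatch_rate <= 1, "max_mismatch_rate in [0,1]"),
            (self.evalue_max > 0, "evalue_max must be > 0"),
            (self.min_word >= 4, "min_word must be >= 4"),
            (0 < self.min_identity <= 1, "min_identity in (0,1]"),
            (self.max_read_gap >= 0, "max_read_gap must be >= 0"),
            (self.max_read_overlap >= 0, "max_read_overlap must be >= 0"),
            (self.junction_tolerance >= 0, "junction_tolerance must be >= 0"),
            (self.flank >= self.min_overhang, "flank must be >= min_overhang"),
            (self.max_residual >= 0, "max_residual must be >= 0"),
            (self.pseudocount >= 0, "pseudocount must be >= 0"),
            (1 < self.efficiency <= 2, "efficiency in (1,2]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("config must be a key-value mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)
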