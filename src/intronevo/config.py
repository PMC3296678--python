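"""Pipeline configuration: every tunable threshold as a named key.

Defaults are the thresholds of the published analysis this pipeline
automates: RBH orthology at e <= 1e-30 / identity >= 70% / coverage >= 80%
(outgroup attachment at the looser 60/60), 30-X artificial introns, a
10-column window for homologous intron positions, insertion-source scans at
coverage >= 90% and e <= 0.1, direct repeats >= 5 bp, and a 1000-shuffle
alignment null.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    # orthology
    rbh_min_identity: float = 70.0
    rbh_min_coverage: float = 80.0
    rbh_max_e: float = 1e-30
    outgroup_min_identity: float = 60.0
    outgroup_min_coverage: float = 60.0
    # alignment / column mapping
    marker_len: int = 30
    max_offset_cols: int = 10
    flank_window: int = 15
    flank_min_identity: float = 0.8
    # QC
    canonical_splice: tuple = (("GT", "AG"),)
    # mechanism scans
    scan_min_coverage: float = 90.0
    scan_max_e: float = 0.1
    scan_min_identity: float = 60.0
    repeat_min_len: int = 5
    repeat_window: int = 30
    tsd_min_len: int = 4
    tsd_max_len: int = 15
    tsd_max_mismatch: int = 1
    n_shuffles: int = 1000
    adjacent_n_perm: int = 10000
    sliding_min_shift: int = 10
    sliding_max_shift: int = 100
    sliding_max_e: float = 0.1

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "canonical_splice" in data:
            data = dict(data)
            data["canonical_splice"] = tuple(
                tuple(pair) for pair in data["canonical_splice"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Short stable hash of the configuration, stamped into outputs."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def splice_set(self) -> set[tuple[str, str]]:
        return {tuple(p) for p in self.canonical_splice}
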