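"""Run configuration: every tunable of the pipeline in one round-trippable
flat key-value file."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .reference import PRIMER_G, PRIMER_H


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Paths and tunables for one pipeline run.

    Defaults are the thresholds standard for short-amplicon 454 diet data:
    98% clustering identity, 40 bp / 4-read cluster filters, and a 95%
    identity over >= 40 aligned columns for reference hits.
    """

    # inputs
    reference_fasta: str = ""
    taxonomy_tsv: str = ""
    reads_path: str = ""
    mids_tsv: str = ""
    metadata_tsv: str = ""
    microhistology_tsv: str = ""
    # reference building
    primer_fwd: str = PRIMER_G
    primer_rev: str = PRIMER_H
    max_primer_mismatch: int = 0
    p6_length_min: int = 50
    p6_length_max: int = 200
    # read processing
    max_mid_mismatch: int = 0
    identity_threshold: float = 0.98
    min_cluster_length: int = 40
    min_cluster_reads: int = 4
    primer_pass_through: bool = False
    # assignment
    min_identity: float = 0.95
    min_aligned: int = 40
    # diet metrics
    major_threshold: float = 0.10
    # community stats
    nmds_k: int = 2
    nmds_starts: int = 20
    nmds_max_iter: int = 200
    nmds_tol: float = 1e-6
    anosim_permutations: int = 999
    chisq_mode: str = "presence"  # presence | reads
    # bookkeeping
    seed: int = 0
    out_dir: str = "trnldiet_out"

    def to_file(self, path) -> None:
        """Write as flat ``key = value`` lines (values JSON-encoded)."""
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {json.dumps(getattr(self, f.name))}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        values = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ConfigError(f"{path}: line {lineno}: unknown key {key!r}")
            try:
                values[key] = json.loads(raw.strip())
            except json.JSONDecodeError as exc:
                raise ConfigError(f"{path}: line {lineno}: bad value: {exc}") from exc
        return cls(**values)
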