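"""Run configuration: validated YAML with explicit defaults.

Unknown keys are an error so a typo like ``flnk_bp`` can never silently
fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import yaml

from .io_formats import SequenceRecord


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass
class PipelineConfig:
    chrom_assembly: str
    contig_sets: list[str]
    reads: str
    catalog: str
    out_dir: str = "fill_out"
    assessor: str = "toy"  # "toy" or an external command template
    aligner: str = "toy"
    assembler: str = "toy"
    flank_bp: int = 50_000
    min_anchor_matches: int = 500
    min_query_coverage: float = 0.8
    min_overlap_bp: int = 1
    assembler_min_olap: int = 500
    include_fragmented: bool = False
    force: bool = False
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        if not self.contig_sets:
            raise ConfigError("at least one contig set is required")
        if self.flank_bp < 0:
            raise ConfigError("flank_bp must be >= 0")
        if self.min_anchor_matches < 0:
            raise ConfigError("min_anchor_matches must be >= 0")
        if not 0 < self.min_query_coverage <= 1:
            raise ConfigError("min_query_coverage must lie in (0, 1]")
        if self.min_overlap_bp < 1:
            raise ConfigError("min_overlap_bp must be >= 1")
        if self.assembler_min_olap < 1:
            raise ConfigError("assembler_min_olap must be >= 1")
        if check_paths:
            for path in [self.chrom_assembly, self.reads, self.catalog, *self.contig_sets]:
                if not Path(path).exists():
                    raise ConfigError(f"input path does not exist: {path}")


_REQUIRED = ("chrom_assembly", "contig_sets", "reads", "catalog")


def load_config(path: str | Path, check_paths: bool = True) -> PipelineConfig:
    """Load and validate a YAML config; relative paths resolve against the file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")

    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing required keys: {missing}")
    if not isinstance(raw["contig_sets"], list):
        raise ConfigError(f"{path}: contig_sets must be a list of paths")

    base = path.parent

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q) if q.is_absolute() else str((base / q).resolve())

    raw = dict(raw)
    raw.setdefault("out_dir", "fill_out")
    for key in ("chrom_assembly", "reads", "catalog", "out_dir"):
        raw[key] = resolve(str(raw[key]))
    raw["contig_sets"] = [resolve(str(p)) for p in raw["contig_sets"]]

    try:
        config = PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    config.validate(check_paths=check_paths)
    return config


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    payload = {f.name: getattr(config, f.name) for f in fields(PipelineConfig)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def merge_contig_sets(
    sets: Sequence[Sequence[SequenceRecord]],
) -> list[SequenceRecord]:
    """Concatenate contig sets, disambiguating colliding ids.

    An id appearing in more than one set is prefixed with its (1-based)
    set index, e.g. two ``ctg1`` become ``s1.ctg1`` and ``s2.ctg1``;
    unique ids are kept as-is.  Order is deterministic: sets in the
    given order, records in their original order.
    """
    if not sets:
        raise ValueError("need at least one contig set")
    seen: dict[str, int] = {}
    for contig_set in sets:
        for rec in contig_set:
            seen[rec.id] = seen.get(rec.id, 0) + 1
    merged: list[SequenceRecord] = []
    for set_idx, contig_set in enumerate(sets, 1):
        for rec in contig_set:
            if seen[rec.id] > 1:
                merged.append(
                    SequenceRecord(f"s{set_idx}.{rec.id}", rec.bases, rec.description)
                )
            else:
                merged.append(rec)
    return merged
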