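"""Run configuration: every tunable threshold of the pipeline in one place."""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass, fields

import yaml

logger = logging.getLogger("circfind")


@dataclass
class AnalysisConfig:
    """Thresholds driving junction detection, filtering and comparison.

    Defaults follow the published T. kodakarensis analysis: 51-nt reads split
    into two exact genome matches of >=20 nt; junctions grouped within +/-5 nt;
    count floors of 100 (total-RNA libraries) and 20 (small-RNA libraries);
    small-RNA candidates longer than 10 kb discarded; a circRNA is called
    depleted in the knockout when its circular-read count falls below 5% of
    wild type; RPKM values below 1 are floored to 0 and genes below 2 RPKM in
    both strains are omitted; differential expression means a strict >2-fold
    change; terminal stems are scored over an 8-nt window with G:U wobble and
    >=3 pairings call a locus circularizable.
    """

    min_segment_len: int = 20
    junction_group_tolerance: int = 5
    min_count_total_rna: int = 100
    min_count_small_rna: int = 20
    max_predicted_len: int = 10_000
    depletion_ratio: float = 0.05
    rpkm_floor: float = 1.0
    rpkm_min_either: float = 2.0
    fold_change_cutoff: float = 2.0
    stem_window: int = 8
    count_gu_wobble: bool = True
    min_stem_pairs_circular: int = 3
    rng_seed: int = 0

    def validate(self, read_length: int | None = None) -> None:
        positive = [
            "min_segment_len",
            "min_count_total_rna",
            "min_count_small_rna",
            "max_predicted_len",
            "stem_window",
            "min_stem_pairs_circular",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.junction_group_tolerance < 0:
            raise ValueError("junction_group_tolerance must be >= 0")
        if not 0.0 < self.depletion_ratio < 1.0:
            raise ValueError("depletion_ratio must lie in (0, 1)")
        if self.fold_change_cutoff <= 0:
            raise ValueError("fold_change_cutoff must be positive")
        if read_length is not None and read_length < 2 * self.min_segment_len:
            logger.warning(
                "read length %d < 2 x min_segment_len (%d): no junction is detectable",
                read_length,
                self.min_segment_len,
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def configure_logging(level: int | str = logging.INFO) -> None:
    """Route pipeline logs to stderr with a level prefix."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("circfind")
    root.handlers[:] = [handler]
    root.setLevel(level)
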