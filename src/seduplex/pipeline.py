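"""End-to-end convenience wrappers: reads -> families -> groups -> counts."""

from __future__ import annotations

import collections
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .consensus import ConsensusConfig, compute_site_counts
from .layout import DEFAULT_LAYOUT, ReadLayout
from .panel import PanelDesign
from .umi import (
    DuplexGroup,
    MergeConfig,
    TaggedRead,
    group_families,
    merge_families,
    pair_duplex,
    tag_reads,
)


@dataclass
class ProcessResult:
    tagged_reads: list[TaggedRead]
    groups: list[DuplexGroup]
    site_counts: pd.DataFrame
    rejects: collections.Counter

    @property
    def duplex_fraction(self) -> float:
        """Share of observed UMIs (groups) with duplex support."""
        n_dup = sum(1 for g in self.groups if g.classification == "DUPLEX")
        return n_dup / len(self.groups) if self.groups else float("nan")


def process_tagged_reads(
    tagged: list[TaggedRead],
    panel: PanelDesign,
    merge_cfg: MergeConfig = MergeConfig(),
    consensus_cfg: ConsensusConfig = ConsensusConfig(),
    rejects: collections.Counter | None = None,
) -> ProcessResult:
    families = group_families(tagged)
    families = merge_families(families, merge_cfg)
    groups = pair_duplex(families, merge_cfg.max_frag_pos_delta)
    counts = compute_site_counts(groups, panel, consensus_cfg)
    return ProcessResult(tagged, groups, counts, rejects or collections.Counter())


def process_fastq(
    fastq1: str | Path,
    alignment: pd.DataFrame,
    panel: PanelDesign,
    merge_cfg: MergeConfig = MergeConfig(),
    consensus_cfg: ConsensusConfig = ConsensusConfig(),
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> ProcessResult:
    """Decode, group, merge, pair and pileup a simulated/aligned run."""
    tagged, rejects = tag_reads(fastq1, alignment, panel, layout)
    return process_tagged_reads(tagged, panel, merge_cfg, consensus_cfg, rejects)
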