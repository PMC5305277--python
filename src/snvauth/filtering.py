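"""The filtering stack that turns raw variant calls into an expressed-SNV profile.

Stages, applied in order by :func:`build_profile`:

1. upstream filter flags + site-quality gates (strand bias FS, quality by
   depth QD),
2. removal of non-SNV records (indels, MNVs),
3. removal of SNV clusters (>= ``cluster_min_snvs`` SNVs within a
   ``cluster_window``-bp window — a signature of alignment artefacts near
   splice junctions),
4. total allelic depth floor,
5. per-transcript highest-impact selection.

Confident homozygous-reference calls carry no alternate allele, so the
SNV-specific stages (cluster, impact) are transparent to them; they are
still subject to the depth floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .types import GenomicPosition, Impact, VariantCall

__all__ = [
    "FilterConfig",
    "SnvProfile",
    "apply_site_quality_filters",
    "remove_snv_clusters",
    "depth_filter",
    "highest_impact_selection",
    "build_profile",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the SNV filtering stack.

    The quality gates follow the GATK hard-filter convention for RNA-seq
    calls: a call fails when FS exceeds ``fs_fail_threshold`` (too much
    strand bias) or QD falls below ``qd_fail_threshold`` (too little
    support per informative read).

    ``fail_missing_stats`` controls the strict/lenient handling of absent
    FS/QD values: strict mode fails them (absent evidence should not pass
    a quality gate), lenient mode (default) passes them — hom-ref calls
    legitimately lack both statistics.
    """

    fs_fail_threshold: float = 30.0
    qd_fail_threshold: float = 2.0
    cluster_window: int = 35
    cluster_min_snvs: int = 3
    min_total_depth: int = 10
    keep_hom_ref: bool = True
    impact_selection: bool = True
    fail_missing_stats: bool = False

    def __post_init__(self) -> None:
        if self.fs_fail_threshold <= 0 or self.qd_fail_threshold <= 0:
            raise ValueError("quality thresholds must be positive")
        if self.cluster_window <= 0 or self.min_total_depth <= 0:
            raise ValueError("cluster_window and min_total_depth must be positive")
        if self.cluster_min_snvs < 2:
            raise ValueError("cluster_min_snvs must be >= 2")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "FilterConfig":
        """Load from JSON or ``key=value`` lines."""
        text = Path(path).read_text()
        if text.lstrip().startswith("{"):
            raw = json.loads(text)
        else:
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, v = line.split("=", 1)
                raw[k.strip()] = v.strip()
        kwargs = {}
        for f_name, f_type in [
            ("fs_fail_threshold", float),
            ("qd_fail_threshold", float),
            ("cluster_window", int),
            ("cluster_min_snvs", int),
            ("min_total_depth", int),
            ("keep_hom_ref", None),
            ("impact_selection", None),
            ("fail_missing_stats", None),
        ]:
            if f_name in raw:
                v = raw[f_name]
                if f_type is None:
                    v = v if isinstance(v, bool) else str(v).lower() in ("1", "true", "yes")
                else:
                    v = f_type(v)
                kwargs[f_name] = v
        return cls(**kwargs)


@dataclass
class SnvProfile:
    """A sample's filtered expressed-SNV set, keyed by unique position."""

    sample_id: str
    calls: dict[GenomicPosition, VariantCall]
    n_input_calls: int
    filter_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def positions(self) -> frozenset[GenomicPosition]:
        return frozenset(self.calls)

    @property
    def n_removed(self) -> int:
        return sum(self.filter_log.values())


def _quality_fail(call: VariantCall, config: FilterConfig) -> bool:
    if not call.passes_upstream_filters:
        return True
    for value, limit, high_is_bad in (
        (call.fisher_strand, config.fs_fail_threshold, True),
        (call.quality_by_depth, config.qd_fail_threshold, False),
    ):
        if value is None:
            if config.fail_missing_stats:
                return True
        elif (value > limit) if high_is_bad else (value < limit):
            return True
    return False


def apply_site_quality_filters(
    calls: Sequence[VariantCall], config: FilterConfig = FilterConfig()
) -> tuple[list[VariantCall], int]:
    """Drop calls failing upstream filter flags or the FS/QD gates.

    Returns the passing calls (order preserved) and the removed count.
    """
    kept = [c for c in calls if not _quality_fail(c, config)]
    return kept, len(calls) - len(kept)


def remove_snv_clusters(
    calls: Sequence[VariantCall], config: FilterConfig = FilterConfig()
) -> tuple[list[VariantCall], int]:
    """Remove every SNV belonging to a dense cluster on its chromosome.

    An SNV is removed iff it lies in some window of ``cluster_window``
    consecutive bases (inclusive span: positions p, q are compatible iff
    ``|p - q| <= window - 1``) containing at least ``cluster_min_snvs``
    SNVs.  Non-SNV records and hom-ref calls are transparent: they
    neither count toward a window nor get removed.  Input order is
    preserved in the output; unsorted input is handled internally.
    """
    def clusterable(c: VariantCall) -> bool:
        return c.is_snv and bool(c.alt_alleles)

    by_chrom: dict[str, list[int]] = {}
    for c in calls:
        if clusterable(c):
            by_chrom.setdefault(c.position.chrom, []).append(c.position.pos)

    doomed: set[GenomicPosition] = set()
    for chrom, positions in by_chrom.items():
        pos = sorted(set(positions))
        n, span = len(pos), config.cluster_window - 1
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j + 1 < n and pos[j + 1] - pos[i] <= span:
                j += 1
            if j - i + 1 >= config.cluster_min_snvs:
                for k in range(i, j + 1):
                    doomed.add(GenomicPosition(chrom, pos[k]))

    kept = [c for c in calls if not (clusterable(c) and c.position in doomed)]
    return kept, len(calls) - len(kept)


def depth_filter(
    calls: Sequence[VariantCall], config: FilterConfig = FilterConfig()
) -> tuple[list[VariantCall], int]:
    """Drop calls whose total allelic depth is below the floor (inclusive keep)."""
    kept = [c for c in calls if c.total_depth >= config.min_total_depth]
    return kept, len(calls) - len(kept)


def highest_impact_selection(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Keep, per transcript, only the variants carrying that transcript's
    maximum impact level.

    A variant survives iff at least one of its annotations reaches the
    maximum impact observed on that annotation's transcript.  Unannotated
    calls (including hom-ref) are retained unconditionally.
    """
    tx_max: dict[str, Impact] = {}
    for c in calls:
        for a in c.annotations:
            prev = tx_max.get(a.transcript_id)
            if prev is None or a.impact > prev:
                tx_max[a.transcript_id] = a.impact
    kept = []
    for c in calls:
        if not c.annotations:
            kept.append(c)
        elif any(a.impact == tx_max[a.transcript_id] for a in c.annotations):
            kept.append(c)
    return kept


def build_profile(
    calls: Sequence[VariantCall],
    config: FilterConfig = FilterConfig(),
    sample_id: str = "sample",
) -> SnvProfile:
    """Run the full filtering stack and key the survivors by unique position.

    If two passing SNVs share a position, the one with greater total depth
    wins (ties: greater QD, then first in input order); the collision is
    counted in the filter log under ``duplicate_position``.
    """
    n_input = len(calls)
    log: dict[str, int] = {}

    current = list(calls)
    if not config.keep_hom_ref:
        current = [c for c in current if c.alt_alleles]
        log["hom_ref_excluded"] = n_input - len(current)

    current, log["site_quality"] = apply_site_quality_filters(current, config)

    snv_only = [c for c in current if c.is_snv]
    log["non_snv"] = len(current) - len(snv_only)
    current = snv_only

    current, log["cluster"] = remove_snv_clusters(current, config)
    current, log["low_depth"] = depth_filter(current, config)

    if config.impact_selection:
        selected = highest_impact_selection(current)
        log["impact_shadowed"] = len(current) - len(selected)
        current = selected

    keyed: dict[GenomicPosition, VariantCall] = {}
    n_dup = 0
    for c in current:
        prev = keyed.get(c.position)
        if prev is None:
            keyed[c.position] = c
        else:
            n_dup += 1
            key = (c.total_depth, c.quality_by_depth or 0.0)
            prev_key = (prev.total_depth, prev.quality_by_depth or 0.0)
            if key > prev_key:
                keyed[c.position] = c
    if n_dup:
        log["duplicate_position"] = n_dup

    return SnvProfile(sample_id=sample_id, calls=keyed, n_input_calls=n_input, filter_log=log)
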