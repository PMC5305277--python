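"""Allele-specific read classification at two proximal variant sites.

When two single-base variants sit close enough that individual reads span
both (e.g. the KRAS codon-12 and codon-13 positions, four bases apart),
each read reports a joint allele state — a two-site haplotype.  Counting
reads per category distinguishes, for instance, a true knockout (no
mutant reads) from a dosage mutant (mutant reads still present), and
reveals whether two mutations ever co-occur on one molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import AlignedRead, GenomicPosition, round_half_up

__all__ = [
    "CATEGORIES",
    "HaplotypeSite",
    "HaplotypeTally",
    "parse_site",
    "classify_read",
    "tally",
    "pooled_proportions",
]

#: joint categories in reporting order: (state at site A, state at site B)
CATEGORIES = ("wt/wt", "wt/mut", "mut/wt", "mut/mut")
OTHER = "other"


@dataclass(frozen=True)
class HaplotypeSite:
    """One single-base variant site with its wild-type and mutant allele."""

    label: str
    position: GenomicPosition
    wt_base: str
    mut_base: str

    def __post_init__(self) -> None:
        if self.wt_base == self.mut_base:
            raise ValueError(f"{self.label}: wt and mut base identical")


def parse_site(spec: str, label: str = "") -> HaplotypeSite:
    """Parse a ``chrom:pos:wt:mut`` site specification."""
    try:
        chrom, pos, wt, mut = spec.split(":")
        return HaplotypeSite(
            label=label or f"{chrom}:{pos}",
            position=GenomicPosition(chrom, int(pos)),
            wt_base=wt.upper(),
            mut_base=mut.upper(),
        )
    except ValueError as exc:
        raise ValueError(f"site must be chrom:pos:wt:mut, got {spec!r}") from exc


@dataclass
class HaplotypeTally:
    """Per-replicate read counts over the joint-allele categories.

    ``total`` sums the four wt/mut combinations; reads carrying a third
    base or an N at either site are counted under ``other`` and excluded
    from the total, and reads not covering both sites are excluded from
    everything.
    """

    replicate_id: str
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    n_other: int = 0
    n_uninformative: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts[c] for c in CATEGORIES)


def classify_read(
    read: AlignedRead, site_a: HaplotypeSite, site_b: HaplotypeSite
) -> Optional[str]:
    """Classify one alignment by its bases at the two sites.

    Returns one of ``CATEGORIES``, ``"other"`` (a base matching neither
    allele at either site), or ``None`` when the read does not carry an
    aligned base at both positions (partial coverage or a spanning
    deletion).
    """
    if site_a.position.chrom != site_b.position.chrom:
        raise ValueError(
            f"sites on different chromosomes: {site_a.position} vs {site_b.position}"
        )
    if site_a.position == site_b.position:
        raise ValueError("the two sites must be distinct positions")
    states = []
    for site in (site_a, site_b):
        base = read.base_at(site.position.pos)
        if base is None:
            return None
        if base == site.wt_base:
            states.append("wt")
        elif base == site.mut_base:
            states.append("mut")
        else:
            return OTHER
    return f"{states[0]}/{states[1]}"


def tally(
    reads: Iterable[AlignedRead],
    site_a: HaplotypeSite,
    site_b: HaplotypeSite,
    replicate_id: str = "",
) -> HaplotypeTally:
    """Count joint-allele categories over all reads of one replicate."""
    t = HaplotypeTally(replicate_id=replicate_id)
    for read in reads:
        cat = classify_read(read, site_a, site_b)
        if cat is None:
            t.n_uninformative += 1
        elif cat == OTHER:
            t.n_other += 1
        else:
            t.counts[cat] += 1
    return t


def pooled_proportions(tallies: Sequence[HaplotypeTally]) -> Optional[dict[str, float]]:
    """Category percentages from counts pooled across replicates.

    Pooling (sum of category counts over sum of totals) weights each
    replicate by its read count; it is not the mean of per-replicate
    proportions.  Percentages are rounded half-up to one decimal.
    Returns ``None`` when the pooled total is zero.
    """
    if not tallies:
        raise ValueError("need at least one tally")
    pooled = {c: sum(t.counts[c] for t in tallies) for c in CATEGORIES}
    total = sum(pooled.values())
    if total == 0:
        return None
    return {c: round_half_up(pooled[c] / total * 100.0, 1) for c in CATEGORIES}
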