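"""Core domain types for RNA-seq based cell line authentication.

The pipeline operates on single-nucleotide variant (SNV) calls derived
from RNA-seq data and compares them against curated per-cell-line
mutation profiles (COSMIC-style exports).  All coordinates are 1-based
and fully closed, matching VCF and COSMIC conventions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Mapping, Optional

__all__ = [
    "Impact",
    "Effect",
    "Zygosity",
    "GenomicPosition",
    "Annotation",
    "VariantCall",
    "ReferenceVariant",
    "ReferenceProfile",
    "PanelLocus",
    "AlignedRead",
    "ComparisonResult",
    "ScreenResult",
    "PanelResult",
    "Verdict",
    "round_half_up",
    "fmt_pct",
]

BASES = frozenset("ACGT")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (half-up), as in printed reports.

    Python's builtin ``round`` uses banker's rounding; report percentages
    follow the half-up convention instead (98.25 -> 98.3 at one decimal).
    """
    if x != x:  # NaN
        return x
    scale = 10.0 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def fmt_pct(fraction: Optional[float], ndigits: int = 1) -> str:
    """Format a fraction as a percentage string; ``None`` renders as NA."""
    if fraction is None:
        return "NA"
    return f"{round_half_up(fraction * 100.0, ndigits):.{ndigits}f}%"


class Impact(enum.IntEnum):
    """SnpEff putative impact, ordered from least to most severe."""

    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    @classmethod
    def from_string(cls, s: str) -> "Impact":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown impact level: {s!r}") from None


class Effect(enum.Enum):
    """Coding consequence class of an SNV."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Zygosity(enum.Enum):
    HET = "het"
    HOM = "hom"
    UNKNOWN = "unknown"


@total_ordering
@dataclass(frozen=True)
class GenomicPosition:
    """A 1-based genomic coordinate on a named chromosome.

    Ordering is (chromosome lexical, position numeric) and total, which is
    all the comparison engine needs: profiles are keyed and intersected on
    unique positions, never on genomic distance across chromosomes.
    """

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    def __lt__(self, other: "GenomicPosition") -> bool:
        return (self.chrom, self.pos) < (other.chrom, other.pos)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class Annotation:
    """One functional annotation (one transcript) of a variant."""

    transcript_id: str
    gene: str
    effect: Effect
    impact: Impact


@dataclass(frozen=True)
class VariantCall:
    """One called site from a VCF record.

    ``alt_alleles`` may be empty for confident homozygous-reference calls,
    which the pipeline retains to increase coverage of reference-profile
    positions.  ``fisher_strand`` (FS) and ``quality_by_depth`` (QD) are
    ``None`` when the caller did not emit them -- absence is never silently
    converted to zero.
    """

    position: GenomicPosition
    ref_allele: str
    alt_alleles: tuple[str, ...] = ()
    genotype: tuple[int, ...] = (0, 0)
    fisher_strand: Optional[float] = None
    quality_by_depth: Optional[float] = None
    allelic_depths: tuple[int, ...] = ()
    filter_flags: frozenset[str] = frozenset()
    annotations: tuple[Annotation, ...] = ()

    def __post_init__(self) -> None:
        n_alleles = 1 + len(self.alt_alleles)
        if self.allelic_depths and len(self.allelic_depths) != n_alleles:
            raise ValueError(
                f"allelic_depths arity {len(self.allelic_depths)} != "
                f"{n_alleles} alleles at {self.position}"
            )
        for i in self.genotype:
            if not (0 <= i < n_alleles):
                raise ValueError(f"genotype index {i} out of range at {self.position}")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    @property
    def is_snv(self) -> bool:
        return all(len(a) == 1 for a in self.alleles)

    @property
    def is_hom_ref(self) -> bool:
        return all(i == 0 for i in self.genotype)

    @property
    def total_depth(self) -> int:
        return sum(self.allelic_depths)

    @property
    def called_alleles(self) -> frozenset[str]:
        """The set of distinct allele strings present in the genotype."""
        return frozenset(self.alleles[i] for i in self.genotype)

    @property
    def passes_upstream_filters(self) -> bool:
        return not self.filter_flags or self.filter_flags == {"PASS"}


@dataclass(frozen=True)
class ReferenceVariant:
    """One known single-base substitution from a reference profile."""

    position: GenomicPosition
    ref_allele: str
    mut_allele: str
    gene: str = ""
    transcript_id: str = ""
    zygosity: Zygosity = Zygosity.UNKNOWN

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES or self.mut_allele not in BASES:
            raise ValueError(
                f"alleles must be single ACGT bases: {self.ref_allele}>{self.mut_allele}"
            )
        if self.ref_allele == self.mut_allele:
            raise ValueError(f"ref and mut allele identical at {self.position}")


@dataclass
class ReferenceProfile:
    """The deduplicated set of known mutations for one cell line.

    Members are unique on (position, mut_allele); a mutation reported on
    several transcripts counts once.
    """

    cell_line: str
    variants: tuple[ReferenceVariant, ...]

    def __post_init__(self) -> None:
        seen: dict[tuple[GenomicPosition, str], ReferenceVariant] = {}
        for v in self.variants:
            seen.setdefault((v.position, v.mut_allele), v)
        self.variants = tuple(seen.values())
        by_pos: dict[GenomicPosition, list[ReferenceVariant]] = {}
        for v in self.variants:
            by_pos.setdefault(v.position, []).append(v)
        self._by_position = by_pos

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> frozenset[GenomicPosition]:
        return frozenset(self._by_position)

    def variants_at(self, position: GenomicPosition) -> tuple[ReferenceVariant, ...]:
        return tuple(self._by_position.get(position, ()))


@dataclass(frozen=True)
class PanelLocus:
    """One locus of an SNP genotyping panel with its expected genotype."""

    locus_id: str
    position: GenomicPosition
    expected_genotype: frozenset[str]

    def __post_init__(self) -> None:
        if not self.expected_genotype <= BASES:
            raise ValueError(f"panel genotype bases must be ACGT: {self.expected_genotype}")


@dataclass(frozen=True)
class AlignedRead:
    """A primary, mapped alignment reduced to its per-position base calls.

    ``aligned_pairs`` maps 1-based reference positions to the read base
    aligned there (reference-strand orientation); positions spanned by a
    deletion are simply absent.
    """

    read_id: str
    chrom: str
    aligned_pairs: Mapping[int, str]

    def base_at(self, pos: int) -> Optional[str]:
        return self.aligned_pairs.get(pos)


@dataclass
class ComparisonResult:
    """Outcome of one SNV-profile vs reference-profile comparison.

    coverage = n_overlap / n_reference (how much of the reference profile
    the expressed SNVs reach); concordance = n_match / n_overlap (how
    often genotypes agree where they can be compared).  Concordance is
    undefined (``None``) when the overlap is empty.
    """

    sample_id: str
    reference_cell_line: str
    n_reference: int
    n_overlap: int
    n_match: int
    n_mismatch: int
    kind: str = "reference"
    match_calls: tuple[VariantCall, ...] = ()
    mismatch_calls: tuple[VariantCall, ...] = ()

    def __post_init__(self) -> None:
        if self.n_match + self.n_mismatch != self.n_overlap:
            raise ValueError("n_match + n_mismatch must equal n_overlap")

    @property
    def coverage(self) -> float:
        if self.n_reference == 0:
            return 0.0
        return self.n_overlap / self.n_reference

    @property
    def concordance(self) -> Optional[float]:
        if self.n_overlap == 0:
            return None
        return self.n_match / self.n_overlap

    @property
    def coverage_pct(self) -> float:
        return round_half_up(self.coverage * 100.0, 1)

    @property
    def concordance_pct(self) -> Optional[float]:
        c = self.concordance
        return None if c is None else round_half_up(c * 100.0, 1)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "reference_cell_line": self.reference_cell_line,
            "kind": self.kind,
            "n_reference": self.n_reference,
            "n_overlap": self.n_overlap,
            "n_match": self.n_match,
            "n_mismatch": self.n_mismatch,
            "coverage_pct": self.coverage_pct,
            "concordance_pct": self.concordance_pct,
        }


@dataclass
class ScreenResult:
    """A contamination screen: the same comparison, read for evidence.

    ``status`` is one of ``clean-ish`` possibilities the evidence supports:
    "no_match" (overlap but nothing matching), "indeterminate" (no
    overlap at all -- absence of evidence, not evidence of absence) or
    "warning" (matches above the alarm threshold).
    """

    result: ComparisonResult
    status: str
    warning: bool

    @property
    def summary(self) -> str:
        return f"{self.result.n_match}/{self.result.n_overlap}"


@dataclass
class PanelResult:
    """Outcome of comparing a profile against an SNP genotyping panel."""

    sample_id: str
    n_loci: int
    n_overlap: int
    n_match: int

    @property
    def summary(self) -> str:
        return f"{self.n_match}/{self.n_overlap}"

    @property
    def concordance(self) -> Optional[float]:
        if self.n_overlap == 0:
            return None
        return self.n_match / self.n_overlap


@dataclass
class Verdict:
    """Authentication decision for one comparison."""

    authenticated: bool
    concordance_threshold: float = 0.90
    min_overlap: int = 25
    notes: tuple[str, ...] = ()
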