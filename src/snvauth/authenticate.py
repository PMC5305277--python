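"""Comparison engine: genotype matching of expressed-SNV profiles against
reference cell-line mutation profiles.

Two statistics summarise a comparison.  *Coverage* is the fraction of a
reference profile's unique SNV positions at which the sample's filtered
call set has a call (overlap / reference size): RNA-seq only sees
expressed transcripts, so coverage around 40% is typical of a genuine
sample.  *Concordance* is the fraction of those overlapping calls whose
genotype matches the reference (matches / overlap): genuine samples sit
in the high 90s, unrelated cell lines around two thirds (shared common
polymorphisms keep it well above zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .filtering import SnvProfile
from .types import (
    ComparisonResult,
    Effect,
    Impact,
    PanelLocus,
    PanelResult,
    ReferenceProfile,
    ReferenceVariant,
    ScreenResult,
    VariantCall,
    Verdict,
    Zygosity,
    round_half_up,
)

__all__ = [
    "match_genotype",
    "compare_to_reference",
    "screen_contaminant",
    "compare_to_panel",
    "pairwise_concordance",
    "characterize",
    "CharacterizationTable",
    "snvs_per_million",
    "verdict",
]

IMPACT_ORDER = [Impact.HIGH, Impact.MODERATE, Impact.LOW, Impact.MODIFIER]
EFFECT_ORDER = [Effect.MISSENSE, Effect.NONSENSE, Effect.SYNONYMOUS, Effect.OTHER]


def match_genotype(call: VariantCall, ref: ReferenceVariant, mode: str = "allele") -> bool:
    """Score one overlapping call against one reference mutation.

    mode="allele" (default): match iff the reference mutant allele is
    among the call's called alleles.  A hom-ref call at a
    reference-mutation position is therefore a mismatch — the sample
    confidently lacks the expected mutation there.

    mode="strict": additionally require zygosity agreement when the
    reference states one (het: both ref and mut allele called; hom: only
    the mut allele).
    """
    if call.position != ref.position:
        raise ValueError(f"position mismatch: call {call.position} vs ref {ref.position}")
    called = call.called_alleles
    if ref.mut_allele not in called:
        return False
    if mode == "strict" and ref.zygosity is not Zygosity.UNKNOWN:
        if ref.zygosity is Zygosity.HET:
            return ref.ref_allele in called
        return called == {ref.mut_allele}
    elif mode not in ("allele", "strict"):
        raise ValueError(f"unknown match mode: {mode!r}")
    return True


def compare_to_reference(
    profile: SnvProfile,
    ref: ReferenceProfile,
    mode: str = "allele",
    count_hom_ref: bool = True,
) -> ComparisonResult:
    """Compare a filtered SNV profile against one reference profile.

    Overlap is counted over unique reference positions; when a position
    carries several reference mutant alleles, matching any one counts as
    a match.  ``count_hom_ref=False`` excludes hom-ref calls from the
    overlap entirely, reproducing an alt-only analysis.

    Raises
    ------
    ValueError
        If the reference profile is empty ("no profile" — nothing to
        authenticate against).
    """
    if len(ref) == 0:
        raise ValueError(f"no profile: reference for {ref.cell_line!r} is empty")

    matches: list[VariantCall] = []
    mismatches: list[VariantCall] = []
    for pos in ref.positions:
        call = profile.calls.get(pos)
        if call is None:
            continue
        if call.is_hom_ref and not count_hom_ref:
            continue
        if any(match_genotype(call, rv, mode=mode) for rv in ref.variants_at(pos)):
            matches.append(call)
        else:
            mismatches.append(call)

    return ComparisonResult(
        sample_id=profile.sample_id,
        reference_cell_line=ref.cell_line,
        n_reference=len(ref),
        n_overlap=len(matches) + len(mismatches),
        n_match=len(matches),
        n_mismatch=len(mismatches),
        match_calls=tuple(matches),
        mismatch_calls=tuple(mismatches),
    )


def screen_contaminant(
    profile: SnvProfile,
    contaminant_ref: ReferenceProfile,
    mode: str = "allele",
    alarm_min_overlap: int = 2,
) -> ScreenResult:
    """Screen a profile against a putative contaminant's reference profile.

    The computation is identical to :func:`compare_to_reference`; the
    reading differs.  Any match with at least ``alarm_min_overlap``
    overlapping positions raises a contamination warning.  Zero overlap
    is labelled indeterminate (insufficient evidence), never clean.
    """
    result = compare_to_reference(profile, contaminant_ref, mode=mode)
    result.kind = "screen"
    if result.n_overlap == 0:
        status, warning = "indeterminate", False
    elif result.n_match > 0 and result.n_overlap >= alarm_min_overlap:
        status, warning = "warning", True
    elif result.n_match > 0:
        status, warning = "possible", False
    else:
        status, warning = "no_match", False
    return ScreenResult(result=result, status=status, warning=warning)


def compare_to_panel(profile: SnvProfile, panel: Sequence[PanelLocus]) -> PanelResult:
    """Compare called genotypes against an SNP genotyping panel.

    Overlap counts panel loci with a profile call; a match requires the
    called genotype to equal the expected one as an unordered base pair.
    """
    n_overlap = n_match = 0
    for locus in panel:
        call = profile.calls.get(locus.position)
        if call is None:
            continue
        n_overlap += 1
        if call.called_alleles == locus.expected_genotype:
            n_match += 1
    return PanelResult(
        sample_id=profile.sample_id, n_loci=len(panel), n_overlap=n_overlap, n_match=n_match
    )


def pairwise_concordance(
    profiles: Sequence[SnvProfile], mode: str = "allele_set"
) -> pd.DataFrame:
    """Transcriptome-wide concordance between every pair of profiles.

    For each ordered pair, overlap is the set of positions called in
    both; a position matches when the two calls carry identical called
    allele sets (``mode="allele_set"``, default) or identical ordered
    genotypes (``mode="genotype"``).  Returned as a square DataFrame of
    percentages rounded to one decimal (NaN where the overlap is empty);
    the matrix is symmetric with a 100.0 diagonal.
    """
    if mode not in ("allele_set", "genotype"):
        raise ValueError(f"unknown pairwise mode: {mode!r}")
    labels = [p.sample_id for p in profiles]
    n = len(profiles)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 100.0
        for j in range(i + 1, n):
            a, b = profiles[i], profiles[j]
            shared = a.positions & b.positions
            if not shared:
                continue
            if mode == "allele_set":
                n_match = sum(
                    1 for p in shared if a.calls[p].called_alleles == b.calls[p].called_alleles
                )
            else:
                n_match = sum(
                    1
                    for p in shared
                    if sorted(a.calls[p].alleles[k] for k in a.calls[p].genotype)
                    == sorted(b.calls[p].alleles[k] for k in b.calls[p].genotype)
                )
            pct = round_half_up(n_match / len(shared) * 100.0, 1)
            out[i, j] = out[j, i] = pct
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class CharacterizationTable:
    """Counts of matching and mismatched SNVs per impact level and effect class.

    Each call contributes its single highest-impact annotation to exactly
    one impact row and one effect row; unannotated calls contribute
    nothing.
    """

    impact_counts: pd.DataFrame
    effect_counts: pd.DataFrame

    @property
    def n_match(self) -> int:
        return int(self.impact_counts["matches"].sum())

    @property
    def n_mismatch(self) -> int:
        return int(self.impact_counts["mismatches"].sum())

    def proportions(self, table: str = "impact") -> pd.DataFrame:
        """Column-wise percentages (one decimal, half-up); NaN for empty columns."""
        counts = self.impact_counts if table == "impact" else self.effect_counts
        out = counts.astype(float).copy()
        for col in out.columns:
            total = out[col].sum()
            out[col] = (
                [round_half_up(v / total * 100.0, 1) for v in out[col]]
                if total > 0
                else np.nan
            )
        return out


def _top_annotation(call: VariantCall):
    return max(call.annotations, key=lambda a: a.impact)


def characterize(
    match_calls: Sequence[VariantCall], mismatch_calls: Sequence[VariantCall]
) -> CharacterizationTable:
    """Tabulate matching vs mismatched SNVs by impact and effect class."""
    impact = pd.DataFrame(
        0, index=[i.name for i in IMPACT_ORDER], columns=["matches", "mismatches"]
    )
    effect = pd.DataFrame(
        0, index=[e.value for e in EFFECT_ORDER], columns=["matches", "mismatches"]
    )
    for col, calls in (("matches", match_calls), ("mismatches", mismatch_calls)):
        for call in calls:
            if not call.annotations:
                continue
            top = _top_annotation(call)
            impact.loc[top.impact.name, col] += 1
            effect.loc[top.effect.value, col] += 1
    return CharacterizationTable(impact_counts=impact, effect_counts=effect)


def snvs_per_million(n_snvs: int, n_reads: int) -> int:
    """SNV yield normalised to sequencing depth: SNVs per 10^6 reads."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    return int(round_half_up(n_snvs / n_reads * 1e6, 0))


def verdict(
    result: ComparisonResult,
    concordance_threshold: float = 0.90,
    min_overlap: int = 25,
) -> Verdict:
    """Authentication decision: concordance above threshold on enough evidence.

    A high concordance over a handful of positions is not persuasive — a
    minimum overlap guards against spurious 100% concordances at tiny
    coverage.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be a positive integer")
    notes: list[str] = []
    conc = result.concordance
    enough = result.n_overlap >= min_overlap
    if not enough:
        notes.append(
            f"insufficient overlap: {result.n_overlap} < {min_overlap} positions"
        )
    concordant = conc is not None and conc >= concordance_threshold
    if conc is not None and concordance_threshold <= conc < concordance_threshold + 0.02:
        notes.append("concordance within 2 points of threshold")
    if conc is None:
        notes.append("no overlapping positions; concordance undefined")
    return Verdict(
        authenticated=bool(concordant and enough),
        concordance_threshold=concordance_threshold,
        min_overlap=min_overlap,
        notes=tuple(notes),
    )
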