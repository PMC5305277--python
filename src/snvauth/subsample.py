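"""Robustness of authentication to sequencing depth, by depth thinning.

The question: as a library is sequenced shallower, the number of filtered
SNVs drops — does concordance with the reference profile stay high?  At
desk scale we model reduced sequencing as binomial thinning of each
call's per-allele read depths (each original read surviving independently
with the given probability), then re-run the filtering stack and the
comparison at every fraction.  This is a surrogate for re-aligning and
re-calling a subsampled FASTQ: it preserves the mechanism under test
(depth-driven SNV loss versus stable concordance) without the calling
machinery, so absolute SNV counts are not comparable with read-level
subsampling — the shape of the curve and the concordance stability are.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .authenticate import compare_to_reference
from .filtering import FilterConfig, build_profile
from .types import ReferenceProfile, VariantCall

__all__ = ["SubsampleResult", "thin_depths", "subsample_curve"]


@dataclass(frozen=True)
class SubsampleResult:
    """One point of a subsampling curve."""

    fraction: float
    n_snvs: int
    concordance: Optional[float]
    seed: int


def thin_depths(
    calls: Sequence[VariantCall], fraction: float, seed: int
) -> list[VariantCall]:
    """Binomially thin every allelic depth; deterministic for a fixed seed.

    Each depth d becomes Binomial(d, fraction).  Alleles whose thinned
    depth reaches zero are dropped from the genotype (remaining allele
    repeated; all-zero collapses to hom-ref), mimicking an allele that a
    shallower experiment would no longer observe.  Genotypes are not
    re-called beyond this drop rule.  ``fraction == 1`` is the identity.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return list(calls)
    rng = np.random.default_rng(seed)
    thinned: list[VariantCall] = []
    for call in calls:
        if not call.allelic_depths:
            thinned.append(call)
            continue
        depths = tuple(int(d) for d in rng.binomial(call.allelic_depths, fraction))
        surviving = [i for i in call.genotype if depths[i] > 0]
        if not surviving:
            genotype = (0,) * max(len(call.genotype), 1)
        elif len(surviving) < len(call.genotype):
            genotype = tuple(sorted(surviving * len(call.genotype)))[: len(call.genotype)]
        else:
            genotype = tuple(surviving)
        thinned.append(replace(call, allelic_depths=depths, genotype=genotype))
    return thinned


def subsample_curve(
    calls: Sequence[VariantCall],
    ref_profile: ReferenceProfile,
    fractions: Sequence[float],
    seed: int,
    config: FilterConfig = FilterConfig(),
    sample_id: str = "sample",
) -> list[SubsampleResult]:
    """Thin, re-filter and re-compare at each fraction.

    One base seed drives the whole curve; each fraction uses a substream
    derived by a fixed offset so curves are reproducible point-by-point.
    Concordance is ``None`` when the thinned profile no longer overlaps
    the reference.
    """
    results = []
    for k, fraction in enumerate(fractions):
        sub_seed = (int(seed) + 1000003 * k) % (2**31)
        thinned = thin_depths(calls, fraction, sub_seed)
        profile = build_profile(thinned, config, sample_id=sample_id)
        if len(profile) and profile.positions & ref_profile.positions:
            comparison = compare_to_reference(profile, ref_profile)
            concordance = comparison.concordance
        else:
            concordance = None
        results.append(
            SubsampleResult(
                fraction=float(fraction),
                n_snvs=len(profile),
                concordance=concordance,
                seed=sub_seed,
            )
        )
    return results
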