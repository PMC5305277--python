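"""Synthetic fixtures with known ground truth for every pipeline input.

Generates, deterministically under a seed: a COSMIC-style reference
profile on a toy chromosome, an annotated single-sample VCF whose calls
realise configured expression, discordance and contamination parameters,
a SAM file of reads spanning two proximal variant sites with configured
joint-allele ratios, and an SNP panel.  Each emitted file comes with a
:class:`GroundTruth` record stating, per position, what was planted and
why — so recovery of the configured parameters by the pipeline can be
checked exactly.

Layout of the toy chromosome ("chrS"): reference-profile variants sit on
a 50-bp grid (wider than the cluster window, so no accidental clusters),
with separate regions for background calls, planted clusters, indels,
low-depth calls, impact-shadowed pairs, quality-gate failures and panel
loci.  Planted filter fodder lives off the reference grid, so the
configured expressed fraction maps one-to-one onto recovered coverage and
the discordance rate onto (1 - concordance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .allele_reads import HaplotypeSite
from .types import GenomicPosition, ReferenceProfile, ReferenceVariant, Zygosity

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_reference_profile",
    "generate_vcf",
    "generate_reads",
    "generate_panel",
]

BASES = "ACGT"
CHROM = "chrS"
GENOME_LENGTH = 10_000_000

# region origins on the toy chromosome
_REF_START = 100_000
_CONTAM_START = 3_000_000
_BACKGROUND_START = 5_000_000
_CLUSTER_START = 7_000_000
_INDEL_START = 7_500_000
_LOW_DEPTH_START = 7_600_000
_SHADOW_START = 7_700_000
_FS_FAIL_START = 7_800_000
_QD_FAIL_START = 7_900_000
_PANEL_START = 8_500_000
_GRID = 50

_EFFECT_TERMS = {
    "missense": "missense_variant",
    "nonsense": "stop_gained",
    "synonymous": "synonymous_variant",
    "other": "intron_variant",
}

# impact / effect proportions typical of filtered expressed coding SNVs
_DEFAULT_IMPACT_MIX = {"HIGH": 0.027, "MODERATE": 0.709, "LOW": 0.259, "MODIFIER": 0.005}
_DEFAULT_EFFECT_MIX = {"missense": 0.707, "nonsense": 0.025, "synonymous": 0.268, "other": 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated experiment.

    Defaults mirror the regime the method targets: a reference profile of
    1000 unique substitutions, 40% of them expressed deeply enough to
    call (the typical transcriptome coverage of genomic variants), a 2%
    genotype-discordance rate at covered positions (authentic-sample
    territory), per-site depths of mean 50 with strong overdispersion,
    no contaminant admixture, and near-1:1:1 two-site haplotype ratios.
    """

    n_reference_variants: int = 1000
    expressed_fraction: float = 0.4
    depth_mean: float = 50.0
    depth_dispersion: float = 2.0
    discordance_rate: float = 0.02
    hom_ref_discordance_share: float = 0.5
    het_fraction: float = 0.8
    contaminant_fraction: float = 0.0
    n_background_calls: int = 200
    cluster_injection: int = 0
    indel_injection: int = 0
    low_depth_injection: int = 0
    shadowed_injection: int = 0
    fs_fail_injection: int = 0
    qd_fail_injection: int = 0
    duplicate_transcript_rows: int = 0
    annotation_impact_mix: dict = field(default_factory=lambda: dict(_DEFAULT_IMPACT_MIX))
    annotation_effect_mix: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECT_MIX))
    haplotype_ratios: tuple = (1 / 3, 1 / 3, 1 / 3, 0.0)
    uninformative_fraction: float = 0.0
    other_base_fraction: float = 0.0
    n_reads: int = 300
    read_length: int = 100
    n_panel_loci: int = 48
    n_panel_covered: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "expressed_fraction",
            "discordance_rate",
            "contaminant_fraction",
            "hom_ref_discordance_share",
            "het_fraction",
            "uninformative_fraction",
            "other_base_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for mix in (self.annotation_impact_mix, self.annotation_effect_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"mix proportions must sum to 1: {mix}")
        if abs(sum(self.haplotype_ratios) - 1.0) > 1e-9:
            raise ValueError("haplotype_ratios must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """A named substream of the config's seed (one per generator)."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class GroundTruth:
    """What was planted where, consistent with the emitted files."""

    entries: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def record(self, position: GenomicPosition, **info) -> None:
        self.entries[str(position)] = info

    def positions_with(self, **criteria) -> list[str]:
        return [
            p
            for p, info in self.entries.items()
            if all(info.get(k) == v for k, v in criteria.items())
        ]

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps({"summary": self.summary, "entries": self.entries}, indent=1) + "\n"
        )


def _draw_allele_pair(rng: np.random.Generator) -> tuple[str, str]:
    ref = BASES[rng.integers(4)]
    mut = BASES[rng.integers(4)]
    while mut == ref:
        mut = BASES[rng.integers(4)]
    return ref, mut


def _third_base(ref: str, mut: str) -> str:
    return next(b for b in BASES if b not in (ref, mut))


# ---------------------------------------------------------------------------
# Reference profile

def generate_reference_profile(
    config: SimulationConfig,
    path: Optional[Union[str, Path]] = None,
    cell_line: str = "SYNTH1",
    region_start: int = _REF_START,
) -> tuple[ReferenceProfile, GroundTruth]:
    """Generate a cell line's reference mutation profile (COSMIC-style TSV).

    Variants occupy a 50-bp grid from ``region_start``; zygosity is het
    with probability ``het_fraction``.  ``duplicate_transcript_rows``
    extra rows repeat existing variants under a second transcript id, to
    exercise reader-side deduplication.
    """
    rng = config.rng(0)
    truth = GroundTruth()
    variants = []
    rows = []
    for i in range(config.n_reference_variants):
        pos = GenomicPosition(CHROM, region_start + i * _GRID)
        ref, mut = _draw_allele_pair(rng)
        zyg = Zygosity.HET if rng.random() < config.het_fraction else Zygosity.HOM
        gene, tx = f"GENE{i:05d}", f"TX{i:06d}"
        variants.append(
            ReferenceVariant(
                position=pos, ref_allele=ref, mut_allele=mut, gene=gene,
                transcript_id=tx, zygosity=zyg,
            )
        )
        rows.append((cell_line, gene, tx, f"{CHROM}:{pos.pos}-{pos.pos}", ref, mut, zyg.value))
        truth.record(pos, category="reference_variant", ref=ref, mut=mut, zygosity=zyg.value)

    for k in range(config.duplicate_transcript_rows):
        v = variants[k % len(variants)]
        rows.append(
            (cell_line, v.gene, f"TXALT{k:04d}",
             f"{CHROM}:{v.position.pos}-{v.position.pos}",
             v.ref_allele, v.mut_allele, v.zygosity.value)
        )

    truth.summary = {
        "cell_line": cell_line,
        "n_unique_variants": len(variants),
        "n_rows": len(rows),
    }
    if path is not None:
        header = "cell_line\tgene\ttranscript\tposition\tref_allele\tmut_allele\tzygosity\n"
        with open(path, "w") as fh:
            fh.write(header)
            for row in rows:
                fh.write("\t".join(row) + "\n")
    return ReferenceProfile(cell_line=cell_line, variants=tuple(variants)), truth


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = f"""\
##fileformat=VCFv4.2
##contig=<ID={CHROM},length={GENOME_LENGTH}>
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher's exact test to detect strand bias">
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c'">
##FILTER=<ID=SnpCluster,Description="Variant in a cluster">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _ann_string(alt: str, effect: str, impact: str, gene: str, tx: str) -> str:
    return (
        f"{alt}|{_EFFECT_TERMS[effect]}|{impact}|{gene}|{gene}|transcript|{tx}"
        f"|protein_coding|1/1|c.1{alt}>N"
    )


def _site_depth(rng: np.random.Generator, config: SimulationConfig, floor: int = 10) -> int:
    """Per-site depth: floor + negative binomial, so expressed calls survive
    the depth gate and the expression parameter maps cleanly onto coverage."""
    mean = max(config.depth_mean - floor, 1.0)
    r = config.depth_dispersion
    p = r / (r + mean)
    return floor + int(rng.negative_binomial(r, p))


class _VcfWriter:
    def __init__(self, sample_id: str):
        self.sample_id = sample_id
        self.records: list[tuple[int, str]] = []

    def add(self, pos, ref, alts, gt, ads, fs, qd, ann="", filt="PASS"):
        info_parts = []
        if fs is not None:
            info_parts.append(f"FS={fs:.3f}")
        if qd is not None:
            info_parts.append(f"QD={qd:.2f}")
        if ann:
            info_parts.append(f"ANN={ann}")
        info = ";".join(info_parts) or "."
        alt_field = ",".join(alts) if alts else "."
        gt_str = "/".join(str(g) for g in gt)
        ad_str = ",".join(str(d) for d in ads)
        line = (
            f"{CHROM}\t{pos}\t.\t{ref}\t{alt_field}\t100\t{filt}\t{info}"
            f"\tGT:AD:DP\t{gt_str}:{ad_str}:{sum(ads)}"
        )
        self.records.append((pos, line))

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                f"{self.sample_id}\n"
            )
            for _, line in sorted(self.records, key=lambda t: t[0]):
                fh.write(line + "\n")


def _sample_mix(rng: np.random.Generator, mix: dict) -> str:
    keys = list(mix)
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def generate_vcf(
    config: SimulationConfig,
    reference_profile: ReferenceProfile,
    path: Union[str, Path],
    contaminant_profile: Optional[ReferenceProfile] = None,
    sample_id: str = "SAMPLE",
) -> GroundTruth:
    """Emit a single-sample annotated VCF realising the configured truth.

    Per reference variant: expressed with probability
    ``expressed_fraction``; an expressed position is discordant with
    probability ``discordance_rate`` (split between a wrong alternate
    allele and a confident hom-ref call), otherwise it carries the
    reference profile's mutant allele with matching zygosity.  Background
    calls, planted filter fodder (clusters, indels, low-depth, shadowed
    impacts, FS/QD gate failures) and contaminant-derived calls are added
    in their own regions per the config.
    """
    rng = config.rng(1)
    truth = GroundTruth()
    w = _VcfWriter(sample_id)
    n_expressed = n_discordant = 0

    def passing_stats():
        return float(rng.uniform(0.0, 10.0)), float(rng.uniform(5.0, 30.0))

    def annotation(alt, idx, impact=None, effect=None, tx=None, gene=None):
        impact = impact or _sample_mix(rng, config.annotation_impact_mix)
        effect = effect or _sample_mix(rng, config.annotation_effect_mix)
        return _ann_string(alt, effect, impact, gene or f"BGENE{idx:05d}", tx or f"BTX{idx:06d}")

    # --- calls at reference-profile positions -----------------------------
    for i, v in enumerate(reference_profile.variants):
        if rng.random() >= config.expressed_fraction:
            truth.record(v.position, category="unexpressed", expressed=False)
            continue
        n_expressed += 1
        depth = _site_depth(rng, config)
        fs, qd = passing_stats()
        if rng.random() < config.discordance_rate:
            n_discordant += 1
            if rng.random() < config.hom_ref_discordance_share:
                w.add(v.position.pos, v.ref_allele, (), (0, 0), (depth,), None, None)
                truth.record(
                    v.position, category="discordant_hom_ref", expressed=True,
                    genotype_bases=[v.ref_allele],
                )
            else:
                wrong = _third_base(v.ref_allele, v.mut_allele)
                ref_d = int(rng.binomial(depth, 0.5))
                w.add(
                    v.position.pos, v.ref_allele, (wrong,), (0, 1),
                    (ref_d, depth - ref_d), fs, qd,
                    ann=annotation(wrong, i, tx=v.transcript_id, gene=v.gene),
                )
                truth.record(
                    v.position, category="discordant_wrong_allele", expressed=True,
                    genotype_bases=sorted({v.ref_allele, wrong}),
                )
        else:
            impact = _sample_mix(rng, config.annotation_impact_mix)
            effect = _sample_mix(rng, config.annotation_effect_mix)
            if v.zygosity is Zygosity.HOM:
                gt, ads = (1, 1), (0, depth)
                bases = [v.mut_allele]
            else:
                ref_d = 1 + int(rng.binomial(depth - 2, 0.5))
                gt, ads = (0, 1), (ref_d, depth - ref_d)
                bases = sorted({v.ref_allele, v.mut_allele})
            w.add(
                v.position.pos, v.ref_allele, (v.mut_allele,), gt, ads, fs, qd,
                ann=_ann_string(v.mut_allele, effect, impact, v.gene, v.transcript_id),
            )
            truth.record(
                v.position, category="authentic_match", expressed=True,
                genotype_bases=bases, impact=impact, effect=effect,
            )

    # --- contaminant admixture --------------------------------------------
    n_contaminant = 0
    if contaminant_profile is not None and config.contaminant_fraction > 0:
        for v in contaminant_profile.variants:
            if rng.random() >= config.expressed_fraction * config.contaminant_fraction:
                continue
            n_contaminant += 1
            depth = _site_depth(rng, config)
            fs, qd = passing_stats()
            ref_d = int(rng.binomial(depth, 0.7))  # minor admixture: skewed to ref
            ref_d = min(ref_d, depth - 1)
            w.add(v.position.pos, v.ref_allele, (v.mut_allele,), (0, 1),
                  (ref_d, depth - ref_d), fs, qd)
            truth.record(v.position, category="contaminant", expressed=True,
                         genotype_bases=sorted({v.ref_allele, v.mut_allele}))

    # --- background calls not in any reference profile --------------------
    for i in range(config.n_background_calls):
        pos = _BACKGROUND_START + i * _GRID
        ref, alt = _draw_allele_pair(rng)
        depth = _site_depth(rng, config)
        fs, qd = passing_stats()
        ref_d = 1 + int(rng.binomial(depth - 2, 0.5))
        w.add(pos, ref, (alt,), (0, 1), (ref_d, depth - ref_d), fs, qd,
              ann=annotation(alt, i))
        truth.record(GenomicPosition(CHROM, pos), category="background", expressed=True,
                     genotype_bases=sorted({ref, alt}))

    # --- planted filter fodder (off the reference grid) -------------------
    for i in range(config.cluster_injection):
        base = _CLUSTER_START + i * 1000
        for off in (0, 12, 24):  # span 25 bp < 35-bp window
            ref, alt = _draw_allele_pair(rng)
            depth = _site_depth(rng, config)
            fs, qd = passing_stats()
            w.add(base + off, ref, (alt,), (0, 1), (depth // 2, depth - depth // 2), fs, qd)
            truth.record(GenomicPosition(CHROM, base + off), category="planted_cluster",
                         expressed=True)

    for i in range(config.indel_injection):
        pos = _INDEL_START + i * 100
        ref, _ = _draw_allele_pair(rng)
        depth = _site_depth(rng, config)
        fs, qd = passing_stats()
        w.add(pos, ref, (ref + "T",), (0, 1), (depth // 2, depth - depth // 2), fs, qd)
        truth.record(GenomicPosition(CHROM, pos), category="planted_indel", expressed=True)

    for i in range(config.low_depth_injection):
        pos = _LOW_DEPTH_START + i * 100
        ref, alt = _draw_allele_pair(rng)
        fs, qd = passing_stats()
        depth = int(rng.integers(2, 10))  # below the depth-10 floor
        w.add(pos, ref, (alt,), (0, 1), (depth // 2, depth - depth // 2), fs, qd)
        truth.record(GenomicPosition(CHROM, pos), category="planted_low_depth", expressed=True)

    for i in range(config.shadowed_injection):
        base = _SHADOW_START + i * 200
        tx, gene = f"SHTX{i:04d}", f"SHGENE{i:04d}"
        for off, impact, cat in ((0, "LOW", "planted_shadowed"), (_GRID, "HIGH", "shadow_anchor")):
            ref, alt = _draw_allele_pair(rng)
            depth = _site_depth(rng, config)
            fs, qd = passing_stats()
            w.add(base + off, ref, (alt,), (0, 1), (depth // 2, depth - depth // 2), fs, qd,
                  ann=_ann_string(alt, "missense", impact, gene, tx))
            truth.record(GenomicPosition(CHROM, base + off), category=cat, expressed=True)

    for i in range(config.fs_fail_injection):
        pos = _FS_FAIL_START + i * 100
        ref, alt = _draw_allele_pair(rng)
        depth = _site_depth(rng, config)
        fs = float(rng.uniform(31.0, 80.0))  # above the FS-30 gate
        qd = float(rng.uniform(5.0, 30.0))
        w.add(pos, ref, (alt,), (0, 1), (depth // 2, depth - depth // 2), fs, qd)
        truth.record(GenomicPosition(CHROM, pos), category="planted_fs_fail", expressed=True)

    for i in range(config.qd_fail_injection):
        pos = _QD_FAIL_START + i * 100
        ref, alt = _draw_allele_pair(rng)
        depth = _site_depth(rng, config)
        fs = float(rng.uniform(0.0, 10.0))
        qd = float(rng.uniform(0.05, 1.9))  # below the QD-2 gate
        w.add(pos, ref, (alt,), (0, 1), (depth // 2, depth - depth // 2), fs, qd)
        truth.record(GenomicPosition(CHROM, pos), category="planted_qd_fail", expressed=True)

    w.write(path)
    truth.summary = {
        "sample_id": sample_id,
        "n_reference_variants": len(reference_profile),
        "n_expressed": n_expressed,
        "n_discordant": n_discordant,
        "n_contaminant": n_contaminant,
        "expressed_fraction": config.expressed_fraction,
        "discordance_rate": config.discordance_rate,
    }
    return truth


# ---------------------------------------------------------------------------
# Reads over two proximal sites

def generate_reads(
    config: SimulationConfig,
    site_a: HaplotypeSite,
    site_b: HaplotypeSite,
    path: Union[str, Path],
) -> GroundTruth:
    """Emit a SAM file of reads spanning two proximal variant sites.

    Each informative read draws its joint category from
    ``haplotype_ratios`` (wt/wt, wt/mut, mut/wt, mut/mut); configured
    fractions of reads cover only the first site (uninformative) or carry
    a third base at the first site ("other").
    """
    rng = config.rng(2)
    lo = min(site_a.position.pos, site_b.position.pos)
    hi = max(site_a.position.pos, site_b.position.pos)
    span = hi - lo + 1
    if span > config.read_length:
        raise ValueError(f"sites {span} bp apart exceed read length {config.read_length}")

    ratios = np.asarray(config.haplotype_ratios, dtype=float)
    categories = [("wt", "wt"), ("wt", "mut"), ("mut", "wt"), ("mut", "mut")]
    planted = {f"{a}/{b}": 0 for a, b in categories}
    n_uninf = n_other = 0

    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{site_a.position.chrom}\tLN:{GENOME_LENGTH}",
    ]
    reads = []
    for i in range(config.n_reads):
        u = rng.random()
        if u < config.uninformative_fraction:
            start = max(1, lo - config.read_length + 1)  # ends at first site only
            seq = ["A"] * config.read_length
            offset = lo - start
            seq[offset] = site_a.wt_base if site_a.position.pos == lo else site_b.wt_base
            n_uninf += 1
        else:
            max_slack = config.read_length - span
            start = lo - int(rng.integers(0, max_slack + 1))
            start = max(1, start)
            seq = ["A"] * config.read_length
            if u < config.uninformative_fraction + config.other_base_fraction:
                seq[site_a.position.pos - start] = _third_base(site_a.wt_base, site_a.mut_base)
                seq[site_b.position.pos - start] = site_b.wt_base
                n_other += 1
            else:
                sa, sb = categories[rng.choice(4, p=ratios / ratios.sum())]
                seq[site_a.position.pos - start] = (
                    site_a.wt_base if sa == "wt" else site_a.mut_base
                )
                seq[site_b.position.pos - start] = (
                    site_b.wt_base if sb == "wt" else site_b.mut_base
                )
                planted[f"{sa}/{sb}"] += 1
        reads.append(
            (start,
             f"read{i:06d}\t0\t{site_a.position.chrom}\t{start}\t60\t"
             f"{config.read_length}M\t*\t0\t0\t{''.join(seq)}\t{'I' * config.read_length}")
        )
    lines.extend(line for _, line in sorted(reads, key=lambda t: t[0]))
    Path(path).write_text("\n".join(lines) + "\n")

    truth = GroundTruth()
    truth.summary = {
        "n_reads": config.n_reads,
        "planted_counts": planted,
        "n_uninformative": n_uninf,
        "n_other": n_other,
        "ratios": list(map(float, ratios)),
    }
    return truth


# ---------------------------------------------------------------------------
# SNP panel

def generate_panel(
    config: SimulationConfig,
    vcf_truth: GroundTruth,
    path: Union[str, Path],
    cell_line: str = "SYNTH1",
) -> GroundTruth:
    """Emit an SNP genotyping panel TSV for one cell line.

    ``n_panel_covered`` loci are placed at expressed, concordant sample
    positions with the truly called genotype (these should all match);
    the remaining loci sit in an untouched region, so the pipeline sees
    them as uncovered.
    """
    rng = config.rng(3)
    covered = vcf_truth.positions_with(category="authentic_match")
    n_cov = min(config.n_panel_covered, len(covered))
    chosen = [covered[int(k)] for k in rng.choice(len(covered), size=n_cov, replace=False)]

    rows = []
    for j, pos_str in enumerate(chosen):
        info = vcf_truth.entries[pos_str]
        chrom, pos = pos_str.split(":")
        bases = info["genotype_bases"]
        gt = "/".join(bases if len(bases) == 2 else bases * 2)[:3]
        rows.append((f"rs{900000 + j}", chrom, pos, gt))
    for j in range(config.n_panel_loci - n_cov):
        pos = _PANEL_START + j * 100
        ref, alt = _draw_allele_pair(rng)
        rows.append((f"rs{100000 + j}", CHROM, str(pos), f"{ref}/{alt}"))

    with open(path, "w") as fh:
        fh.write(f"locus_id\tchrom\tpos\t{cell_line}\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    truth = GroundTruth()
    truth.summary = {
        "n_loci": len(rows),
        "n_covered": n_cov,
        "covered_loci": chosen,
        "cell_line": cell_line,
    }
    return truth
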