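"""Readers and writers for the external formats the pipeline touches.

Variant calls come in as annotated single-sample VCF (GATK HaplotypeCaller
style: GT/AD per sample, FS/QD/ANN in INFO); reference mutation profiles
as COSMIC-export-like TSV; SNP genotyping panels as TSV; reads as SAM
text.  Reports go out as TSV or JSON.

Column naming of COSMIC exports varies between releases, so the reference
profile reader accepts a small set of aliases per column; the canonical
dialect is the one :mod:`snvauth.synthetic` writes.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import pysam

from .types import (
    AlignedRead,
    Annotation,
    ComparisonResult,
    Effect,
    GenomicPosition,
    Impact,
    PanelLocus,
    PanelResult,
    ReferenceProfile,
    ReferenceVariant,
    ScreenResult,
    Verdict,
    Zygosity,
    fmt_pct,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VcfParseError",
    "RecordError",
    "NoProfileError",
    "read_vcf",
    "parse_annotation",
    "read_reference_profile",
    "read_panel",
    "read_alignments",
    "write_report",
    "read_report",
    "write_matrix",
]


class VcfParseError(ValueError):
    """A VCF could not be parsed; carries the offending line when known."""


class RecordError(ValueError):
    """A single record is internally inconsistent (e.g. AD arity)."""


class NoProfileError(LookupError):
    """The requested cell line has no rows in the reference profile file.

    Distinct from an empty profile: the file simply does not know the line.
    """


# ---------------------------------------------------------------------------
# SnpEff ANN parsing

_EFFECT_MAP = {
    "missense_variant": Effect.MISSENSE,
    "stop_gained": Effect.NONSENSE,
    "synonymous_variant": Effect.SYNONYMOUS,
}

#: minimum number of pipe-delimited fields for an ANN entry
#: (allele|annotation|impact|gene_name|gene_id|feature_type|feature_id|...)
_ANN_MIN_FIELDS = 7


def parse_annotation(ann_field: str) -> list[Annotation]:
    """Parse a SnpEff ``ANN`` INFO string into :class:`Annotation` objects.

    Entries are comma-separated; fields within an entry pipe-separated.
    The SnpEff effect vocabulary is collapsed onto four classes
    (missense / nonsense / synonymous / other); compound effects joined
    with ``&`` map to the first recognised term, else ``other``.

    Raises
    ------
    ValueError
        If an entry has too few fields or an unknown impact level.
    """
    if not ann_field:
        return []
    annotations = []
    for entry in ann_field.split(","):
        fields = entry.split("|")
        if len(fields) < _ANN_MIN_FIELDS:
            raise ValueError(f"ANN entry has {len(fields)} fields (< {_ANN_MIN_FIELDS}): {entry!r}")
        effect = Effect.OTHER
        for term in fields[1].split("&"):
            if term in _EFFECT_MAP:
                effect = _EFFECT_MAP[term]
                break
        impact = Impact.from_string(fields[2])
        annotations.append(
            Annotation(transcript_id=fields[6], gene=fields[3], effect=effect, impact=impact)
        )
    return annotations


# ---------------------------------------------------------------------------
# VCF

def read_vcf(
    path: Union[str, Path],
    include_hom_ref: bool = False,
    sample: Optional[str] = None,
    strict: bool = False,
) -> list["VariantCall"]:
    """Read single-sample variant calls from a VCF 4.x file.

    Parameters
    ----------
    path
        VCF file (plain text).
    include_hom_ref
        Keep records without alternate alleles (confident homozygous
        reference calls); dropped otherwise.
    sample
        Sample name to read; defaults to the first sample.
    strict
        If true, a record whose allele-depth arity disagrees with its
        allele count raises :class:`RecordError`; otherwise the record is
        skipped with a logged warning.

    Missing FS/QD statistics are kept as ``None`` ("absent"), never zero.
    Input order is preserved.
    """
    from .types import VariantCall

    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if not samples:
        raise VcfParseError(f"{path}: VCF has no sample columns")
    if sample is None:
        sample = samples[0]
    elif sample not in samples:
        raise VcfParseError(f"{path}: sample {sample!r} not in header {samples}")

    calls: list[VariantCall] = []
    for i, rec in enumerate(vcf, start=1):
        try:
            call = _record_to_call(rec, sample)
        except RecordError as exc:
            if strict:
                raise
            logger.warning("skipping record %d at %s:%s: %s", i, rec.chrom, rec.pos, exc)
            continue
        if call is None:
            continue
        if not call.alt_alleles and not include_hom_ref:
            continue
        calls.append(call)
    return calls


def _record_to_call(rec, sample: str):
    from .types import VariantCall

    fmt = rec.samples[sample]
    gt = fmt.get("GT")
    if gt is None or any(g is None for g in gt):
        raise RecordError("missing or partial genotype")
    alts = tuple(a for a in (rec.alts or ()) if a is not None and a != "*")
    n_alleles = 1 + len(alts)

    ad = fmt.get("AD")
    if ad is None or all(d is None for d in ad):
        depths: tuple[int, ...] = ()
    else:
        depths = tuple(int(d) if d is not None else 0 for d in ad)
        if len(depths) != n_alleles:
            raise RecordError(f"AD arity {len(depths)} != {n_alleles} alleles")

    fs = rec.info.get("FS")
    qd = rec.info.get("QD")
    ann = rec.info.get("ANN")
    if ann is None:
        ann_str = ""
    elif isinstance(ann, tuple):
        ann_str = ",".join(ann)
    else:
        ann_str = str(ann)

    filters = frozenset(rec.filter.keys())
    try:
        return VariantCall(
            position=GenomicPosition(rec.chrom, rec.pos),
            ref_allele=rec.ref,
            alt_alleles=alts,
            genotype=tuple(int(g) for g in gt),
            fisher_strand=float(fs) if fs is not None else None,
            quality_by_depth=float(qd) if qd is not None else None,
            allelic_depths=depths,
            filter_flags=filters,
            annotations=tuple(parse_annotation(ann_str)),
        )
    except ValueError as exc:
        raise RecordError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Reference (COSMIC-style) profiles

_COLUMN_ALIASES = {
    "cell_line": ("cell_line", "sample name", "sample_name", "sample"),
    "gene": ("gene", "gene name", "gene_name"),
    "transcript": ("transcript", "transcript_id", "accession number"),
    "position": ("position", "mutation genome position", "genome_position"),
    "chrom": ("chrom", "chromosome", "chr"),
    "pos": ("pos", "start"),
    "ref_allele": ("ref_allele", "ref", "wt_allele", "wt"),
    "mut_allele": ("mut_allele", "mut", "alt", "alt_allele"),
    "zygosity": ("zygosity", "mutation zygosity"),
    "strand": ("strand", "mutation strand"),
}

_ZYGOSITY_MAP = {
    "het": Zygosity.HET,
    "heterozygous": Zygosity.HET,
    "hom": Zygosity.HOM,
    "homozygous": Zygosity.HOM,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _find_column(df: pd.DataFrame, key: str) -> Optional[str]:
    lowered = {c.lower().strip(): c for c in df.columns}
    for alias in _COLUMN_ALIASES[key]:
        if alias in lowered:
            return lowered[alias]
    return None


def _parse_coordinate(value: str) -> GenomicPosition:
    """Parse a ``chrom:start-end`` coordinate; start must equal end (SNV)."""
    text = str(value).strip()
    try:
        chrom, span = text.split(":")
        if "-" in span:
            start_s, end_s = span.split("-")
        else:
            start_s = end_s = span
        start, end = int(start_s), int(end_s)
    except (ValueError, AttributeError):
        raise ValueError(f"unparseable coordinate: {value!r}") from None
    if start != end:
        raise ValueError(f"coordinate spans {end - start + 1} bases, not a substitution: {value!r}")
    return GenomicPosition(chrom, start)


def read_reference_profile(
    path: Union[str, Path], cell_line: str, on_bad_row: str = "raise"
) -> ReferenceProfile:
    """Load one cell line's mutation profile from a COSMIC-style TSV.

    Only single-base substitutions are retained, deduplicated to unique
    (position, mutant allele) pairs — a mutation listed on several
    transcripts counts once.  Rows on the reverse strand (optional
    ``strand`` column) are normalised to forward-strand alleles.

    Parameters
    ----------
    on_bad_row
        "raise" (default) or "skip" rows with unparseable coordinates or
        alleles.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    col_line = _find_column(df, "cell_line")
    if col_line is None:
        raise ValueError(f"{path}: no cell line column found")
    rows = df[df[col_line] == cell_line]
    if rows.empty:
        raise NoProfileError(f"no profile for cell line {cell_line!r} in {path}")

    col_position = _find_column(df, "position")
    col_chrom, col_pos = _find_column(df, "chrom"), _find_column(df, "pos")
    col_ref = _find_column(df, "ref_allele")
    col_mut = _find_column(df, "mut_allele")
    col_gene = _find_column(df, "gene")
    col_tx = _find_column(df, "transcript")
    col_zyg = _find_column(df, "zygosity")
    col_strand = _find_column(df, "strand")
    if col_ref is None or col_mut is None:
        raise ValueError(f"{path}: reference/mutant allele columns not found")
    if col_position is None and (col_chrom is None or col_pos is None):
        raise ValueError(f"{path}: no coordinate column found")

    variants = []
    for idx, row in rows.iterrows():
        try:
            if col_position is not None and row[col_position]:
                position = _parse_coordinate(row[col_position])
            else:
                position = GenomicPosition(row[col_chrom], int(row[col_pos]))
            ref, mut = row[col_ref].strip().upper(), row[col_mut].strip().upper()
            if col_strand is not None and row[col_strand].strip() == "-":
                ref, mut = ref.translate(_COMPLEMENT), mut.translate(_COMPLEMENT)
            if len(ref) != 1 or len(mut) != 1:
                raise ValueError(f"not a single-base substitution: {ref}>{mut}")
            zyg = Zygosity.UNKNOWN
            if col_zyg is not None:
                zyg = _ZYGOSITY_MAP.get(row[col_zyg].strip().lower(), Zygosity.UNKNOWN)
            variants.append(
                ReferenceVariant(
                    position=position,
                    ref_allele=ref,
                    mut_allele=mut,
                    gene=row[col_gene] if col_gene else "",
                    transcript_id=row[col_tx] if col_tx else "",
                    zygosity=zyg,
                )
            )
        except ValueError as exc:
            if on_bad_row == "raise":
                raise ValueError(f"{path} row {idx}: {exc}") from exc
            logger.warning("%s row %d skipped: %s", path, idx, exc)

    profile = ReferenceProfile(cell_line=cell_line, variants=tuple(variants))
    logger.info("profile %s: %d unique variants (%d rows)", cell_line, len(profile), len(rows))
    return profile


# ---------------------------------------------------------------------------
# SNP panel

def read_panel(path: Union[str, Path], cell_line: Optional[str] = None) -> list[PanelLocus]:
    """Read an SNP genotyping panel TSV.

    Layout: ``locus_id``, ``chrom``, ``pos`` plus either a single
    ``genotype`` column or one genotype column per cell line (selected via
    ``cell_line``).  Genotypes are unordered base pairs written ``A/G``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: panel requires columns {sorted(required)}")
    if cell_line is not None:
        if cell_line not in df.columns:
            raise NoProfileError(f"no genotype column for cell line {cell_line!r} in {path}")
        gt_col = cell_line
    elif "genotype" in df.columns:
        gt_col = "genotype"
    else:
        raise ValueError(f"{path}: no 'genotype' column and no cell line given")

    loci = []
    for _, row in df.iterrows():
        bases = frozenset(str(row[gt_col]).strip().upper().split("/"))
        loci.append(
            PanelLocus(
                locus_id=str(row["locus_id"]),
                position=GenomicPosition(str(row["chrom"]), int(row["pos"])),
                expected_genotype=bases,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# SAM

def read_alignments(path: Union[str, Path]) -> list[AlignedRead]:
    """Read primary, mapped alignments from a SAM file.

    Secondary, supplementary and unmapped records are discarded.  Each
    surviving alignment is reduced to its mapping from 1-based reference
    position to read base (deleted positions absent).
    """
    reads: list[AlignedRead] = []
    n_records = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            n_records += 1
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence
            if seq is None:
                continue
            pairs = {
                ref_pos + 1: seq[q_pos].upper()
                for q_pos, ref_pos in aln.get_aligned_pairs(matches_only=True)
            }
            reads.append(
                AlignedRead(read_id=aln.query_name, chrom=aln.reference_name, aligned_pairs=pairs)
            )
    if n_records and not reads:
        warnings.warn(f"{path}: no mapped primary alignments", stacklevel=2)
    return reads


# ---------------------------------------------------------------------------
# Reports

def _result_rows(result) -> dict:
    if isinstance(result, ComparisonResult):
        d = result.to_dict()
    elif isinstance(result, ScreenResult):
        d = result.result.to_dict()
        d.update({"status": result.status, "warning": result.warning, "summary": result.summary})
    elif isinstance(result, PanelResult):
        d = {
            "sample_id": result.sample_id,
            "kind": "panel",
            "n_loci": result.n_loci,
            "n_overlap": result.n_overlap,
            "n_match": result.n_match,
            "summary": result.summary,
            "concordance_pct": None
            if result.concordance is None
            else round(result.concordance * 100, 1),
        }
    elif isinstance(result, Verdict):
        d = {
            "authenticated": result.authenticated,
            "concordance_threshold": result.concordance_threshold,
            "min_overlap": result.min_overlap,
            "notes": list(result.notes),
        }
    elif isinstance(result, dict):
        d = result
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")
    return d


def write_report(result, path: Union[str, Path], format: str = "tsv") -> None:
    """Write a comparison/screen/panel result (or a plain dict) to disk.

    Counts are written loss-free; percentages are already rounded to one
    decimal by the result objects.
    """
    d = _result_rows(result)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(d, indent=2, default=str) + "\n")
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for k, v in d.items():
                if isinstance(v, (list, tuple)):
                    v = ";".join(str(x) for x in v)
                w.writerow([k, "NA" if v is None else v])
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: Union[str, Path]) -> dict:
    """Read back a report written by :func:`write_report` (either format)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        return json.loads(text)
    out: dict = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        k, v = line.split("\t", 1)
        if v == "NA":
            out[k] = None
        else:
            try:
                out[k] = int(v)
            except ValueError:
                try:
                    out[k] = float(v)
                except ValueError:
                    out[k] = {"True": True, "False": False}.get(v, v)
    return out


def write_matrix(matrix: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a pairwise-concordance matrix as a labelled TSV."""
    matrix.to_csv(path, sep="\t", na_rep="NA")
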