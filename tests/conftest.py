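import pytest

from snvauth.types import Annotation, Effect, GenomicPosition, Impact, VariantCall

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000000>
##contig=<ID=chr2,length=100000000>
##contig=<ID=chrS,length=10000000>
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">
##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
##FILTER=<ID=SnpCluster,Description="SNV cluster">
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf(path, body_lines):
    """Write a small VCF from raw body lines (tab-joined already)."""
    path.write_text(VCF_HEADER + "\n".join(body_lines) + "\n")
    return path


def make_call(
    chrom="chr1",
    pos=100,
    ref="A",
    alts=("G",),
    gt=(0, 1),
    fs=1.0,
    qd=20.0,
    depths=None,
    filters=(),
    annotations=(),
):
    """Construct a VariantCall with sensible defaults for filter tests."""
    alts = tuple(alts)
    if depths is None:
        depths = (10,) * (1 + len(alts))
    return VariantCall(
        position=GenomicPosition(chrom, pos),
        ref_allele=ref,
        alt_alleles=alts,
        genotype=tuple(gt),
        fisher_strand=fs,
        quality_by_depth=qd,
        allelic_depths=tuple(depths),
        filter_flags=frozenset(filters),
        annotations=tuple(annotations),
    )


def ann(tx="TX1", gene="G1", effect=Effect.MISSENSE, impact=Impact.MODERATE):
    return Annotation(transcript_id=tx, gene=gene, effect=effect, impact=impact)


@pytest.fixture
def call_factory():
    return make_call
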