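import numpy as np
import pytest

from ffpeqc.variant_io import SampleMeta, VariantRecord, VariantSet

TINY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
1\t100\t.\tC\tT\t50\t.\tMQ=60\tGT:DP:AD\t0/1:50:25,25
1\t200\t.\tC\tT,G\t50\t.\tMQ=58.5\tGT:DP:AD\t1/2:60:0,30,30
1\t300\t.\tCT\tC\t50\t.\tMQ=44\tGT:DP:AD\t0/1:40:20,20
2\t50\t.\tG\tA\t50\t.\tMQ=60;DP=33\tGT\t1/1
2\t60\t.\tA\tAGG\t50\t.\tMQ=12\tGT:DP:AD\t0/1:80:40,40
2\t70\t.\tT\tC\t50\t.\tMQ=60\tGT:DP:AD\t./.:90:45,45
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    """Hand-written 6-row VCF: multi-allelic, indel, INFO-only DP, missing GT."""
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


def make_record(chrom="chr1", pos=100, ref="C", alt="T", gt=(0, 1),
                dp=50, mq=60.0, ad="auto", alts=None):
    alts = alts if alts is not None else (alt,)
    if ad == "auto":
        ad = None
        if dp is not None:
            ad = tuple([dp - 10 * len(alts)] + [10] * len(alts))
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
                         genotype=gt, dp=dp, mq=mq, ad=ad)


def make_set(records, sample_id="S", condition="FF", **meta_kw):
    kit = meta_kw.pop("kit", "FF-Micro" if condition == "FF" else "GeneRead")
    vs = VariantSet(meta=SampleMeta(sample_id=sample_id, condition=condition,
                                    kit=kit, **meta_kw))
    for rec in records:
        vs.add(rec)
    return vs


def random_snv_set(rng, n, sample_id="R", condition="FF", pos_space=500):
    """Random single-alt SNV records in a small coordinate space."""
    positions = rng.choice(pos_space, size=n, replace=False)
    records = []
    bases = "ACGT"
    for p in positions:
        ref = bases[rng.integers(0, 4)]
        alt = [b for b in bases if b != ref][rng.integers(0, 3)]
        gt = (0, 1) if rng.random() < 0.6 else (1, 1)
        records.append(make_record(pos=int(p) + 1, ref=ref, alt=alt, gt=gt))
    return make_set(records, sample_id=sample_id, condition=condition)


# --- independent brute-force oracle (no dict indexing) ----------------------

def brute_force_pair_counts(ff_records, ffpe_records, mode="genotype"):
    """Nested-loop concordance counts; deliberately naive."""
    n_pos = n_co = 0
    for a in ff_records:
        for b in ffpe_records:
            if (a.chrom, a.pos, a.ref) == (b.chrom, b.pos, b.ref):
                n_pos += 1
                same = set(a.alts) == set(b.alts)
                if mode == "genotype":
                    same = same and sorted(a.genotype) == sorted(b.genotype)
                n_co += same
    return n_pos, n_co, n_pos - n_co


@pytest.fixture
def rng():
    return np.random.default_rng(20_180_404)
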