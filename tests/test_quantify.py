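import numpy as np
import pandas as pd
import pytest

from strandtile.core_model import GeneModel, Genome, GenomeSequence, map_probes
from strandtile.normalization import NormalizedSignal
from strandtile.quantify import (
    call_antisense,
    classify_segment,
    classify_segments,
    gene_strand_expression,
    segment_mean,
    splicing_index,
)
from strandtile.segmentation import Segment
from strandtile.synthetic_data import (
    TranscriptTruth,
    design_tiling_probes,
    simulate_intensities,
    SimConfig,
)
from strandtile.normalization import normalize_to_gdna


def make_segment(chrom, strand, start, end, mean=2.0, first=0, last=3):
    return Segment(chrom, strand, first, last, start, end, mean, last - first + 1)


@pytest.fixture
def toy_signal(rng):
    """A 4 kb genome, one + strand gene, handcrafted probe values."""
    seq = "".join(rng.choice(list("ACGT"), 4_000))
    genome = Genome([GenomeSequence("c", seq)])
    probes, _ = map_probes(design_tiling_probes(genome, 50), genome)
    gene = GeneModel("g1", "c", "+", 1_000, 2_000)
    values = {}
    for p in probes:
        if p.strand == "+" and 1_000 <= p.start and p.end <= 2_000:
            values[p.probe_id] = 3.0
        elif p.strand == "-" and 1_000 <= p.start and p.end <= 2_000:
            values[p.probe_id] = 0.2
        else:
            values[p.probe_id] = 0.0
    df = pd.DataFrame({"s": pd.Series(values)})
    df.index.name = "probe_id"
    return genome, probes, gene, NormalizedSignal(df, {"s": 0.0})


def test_gene_strand_expression_plain_case(toy_signal):
    _, probes, gene, signal = toy_signal
    df = gene_strand_expression([gene], signal, probes, "s")
    assert df.loc["g1", "sense_avg"] == pytest.approx(3.0)
    assert df.loc["g1", "antisense_avg"] == pytest.approx(0.2)


def test_gene_without_probes_flagged_missing(toy_signal):
    _, probes, _, signal = toy_signal
    tiny = GeneModel("tiny", "c", "+", 10, 40)  # too short to contain a probe fully
    df = gene_strand_expression([tiny], signal, probes, "s")
    assert np.isnan(df.loc["tiny", "sense_avg"])
    assert np.isnan(df.loc["tiny", "antisense_avg"])


def test_segment_mean_matches_definition(toy_signal, rng):
    _, probes, _, signal = toy_signal
    plist = probes.probes_for("c", "+")
    # set random values on a 10-probe window and check against a naive sum
    ids = [p.probe_id for p in plist[5:15]]
    vals = rng.normal(size=10)
    signal.values.loc[ids, "s"] = vals
    seg = Segment("c", "+", 5, 14, plist[5].start, plist[14].end, 0.0, 10)
    naive = sum(vals) / len(vals)
    assert segment_mean(seg, signal, probes, "s") == pytest.approx(naive, abs=1e-12)


def test_single_probe_segment_mean(toy_signal):
    _, probes, _, signal = toy_signal
    plist = probes.probes_for("c", "+")
    seg = Segment("c", "+", 3, 3, plist[3].start, plist[3].end, 0.0, 1)
    assert segment_mean(seg, signal, probes, "s") == pytest.approx(
        signal.values.loc[plist[3].probe_id, "s"]
    )


def test_classify_segment_categories(toy_signal):
    _, _, gene, _ = toy_signal
    anti = make_segment("c", "-", 1_000, 2_000)
    assert classify_segment(anti, [gene]).category == "antisense"
    assert classify_segment(anti, [gene]).gene_id == "g1"
    sense = make_segment("c", "+", 1_000, 2_000)
    assert classify_segment(sense, [gene]).category == "sense"
    intergenic = make_segment("c", "+", 3_000, 3_500)
    assert classify_segment(intergenic, [gene]).category == "non_annotated"
    barely = make_segment("c", "+", 1_960, 3_000)  # 40 nt overlap < 50 nt minimum
    assert classify_segment(barely, [gene]).category == "non_annotated"


def test_classify_segment_max_overlap_matches_bruteforce(rng):
    genes = [
        GeneModel("a", "c", "+", 100, 700),
        GeneModel("b", "c", "-", 600, 1_400),
        GeneModel("d", "c", "+", 1_350, 2_000),
    ]
    for _ in range(50):
        s = int(rng.integers(0, 1_900))
        e = s + int(rng.integers(100, 900))
        strand = "+" if rng.random() < 0.5 else "-"
        seg = make_segment("c", strand, s, e)
        ann = classify_segment(seg, genes)
        # oracle: interval arithmetic over all genes
        best, best_key = None, (-1.0, False, -1)
        for g in genes:
            ov = max(0, min(e, g.cds_end) - max(s, g.cds_start))
            if ov < 50:
                continue
            rec = min(ov / (g.cds_end - g.cds_start), ov / (e - s))
            key = (rec, g.strand == strand, ov)
            if key > best_key:
                best, best_key = g, key
        if best is None:
            assert ann.category == "non_annotated"
        else:
            assert ann.gene_id == best.gene_id
            assert ann.category == ("sense" if best.strand == strand else "antisense")


def test_call_antisense_threshold_and_category_gate(toy_signal):
    _, _, gene, _ = toy_signal
    below = make_segment("c", "-", 1_000, 2_000, mean=0.99)
    above = make_segment("c", "-", 1_000, 2_000, mean=1.01)
    sense = make_segment("c", "+", 1_000, 2_000, mean=5.0)
    anns = classify_segments([below, above, sense], [gene])
    calls = call_antisense(anns, [gene], threshold=1.0)
    assert [c.segment.mean_intensity for c in calls] == [1.01]
    assert calls[0].gene_id == "g1"
    assert calls[0].covers_full_cds


def test_raising_threshold_shrinks_call_set(toy_signal, rng):
    _, _, gene, _ = toy_signal
    segs = [
        make_segment("c", "-", 1_000, 2_000, mean=float(m))
        for m in rng.uniform(0, 3, 20)
    ]
    anns = classify_segments(segs, [gene])
    lower = {id(c.segment) for c in call_antisense(anns, [gene], 0.8)}
    higher = {id(c.segment) for c in call_antisense(anns, [gene], 1.5)}
    assert higher <= lower


def test_planted_origin_classes_recovered(small_run):
    truth = small_run.truth
    by_gene = {}
    for c in small_run.calls["veg"]:
        cur = by_gene.get(c.gene_id)
        if cur is None or c.segment.n_probes > cur.segment.n_probes:
            by_gene[c.gene_id] = c
    for gid in truth.genes_by_architecture("meiotic_discrete"):
        assert by_gene[gid].origin == "discrete_unit"
    for gid in truth.genes_by_architecture("meiotic_utr3"):
        assert by_gene[gid].origin == "utr3_extension"


def test_gene_in_one_segment_matches_segment_mean(small_run):
    """Per-gene averaging is segmentation-independent: a gene fully inside
    one segment has sense_avg equal to that segment's mean when the segment
    contains exactly the gene's probes."""
    probes = small_run.probes
    col = small_run.signal.values["veg"]
    for seg in small_run.segments["veg"]:
        for g in small_run.truth.genes:
            if (
                g.chrom == seg.chrom
                and g.strand == seg.strand
                and seg.genomic_start <= g.cds_start
                and seg.genomic_end >= g.cds_end
            ):
                plist = probes.probes_for(seg.chrom, seg.strand)
                members = plist[seg.first_probe_index : seg.last_probe_index + 1]
                inside = [
                    p for p in members if p.start >= g.cds_start and p.end <= g.cds_end
                ]
                if len(inside) == seg.n_probes:
                    got = small_run.gene_table.loc[g.gene_id, "veg_sense"]
                    assert got == pytest.approx(seg.mean_intensity, abs=1e-9)


def _spliced_setup(rng, intron_abundance):
    seq = "".join(rng.choice(list("ACGT"), 4_000))
    genome = Genome([GenomeSequence("c", seq)])
    probes, _ = map_probes(design_tiling_probes(genome, 25), genome)
    gene = GeneModel(
        "g", "c", "+", 1_000, 2_400, exons=((1_000, 1_500), (1_900, 2_400))
    )
    cfg = SimConfig(
        seed=5, genome_length=4_000, noise_cv=0.05, affinity_sigma=0.3,
        conditions=("veg",),
        n_constitutive=0, n_meiotic_discrete=0, n_meiotic_utr3=0, n_fkh2_targets=0,
        n_new_antisense=0, n_internal_bidir=0, n_intron_spliced=0,
        n_intron_unspliced=0, n_twofold=0,
    )
    transcripts = [
        TranscriptTruth(
            "t.exons", "c", "+", 1_000, 2_400, "sense_mRNA", True, {"veg": 0.7},
            "g", blocks=gene.exons,
        )
    ]
    if intron_abundance:
        transcripts.append(
            TranscriptTruth(
                "t.intron", "c", "+", 1_500, 1_900, "noncoding", False,
                {"veg": intron_abundance}, "g",
            )
        )
    matrix = simulate_intensities(transcripts, probes, cfg)
    signal = normalize_to_gdna(matrix, None, probes, [gene])
    return gene, signal, probes


def test_splicing_index_spliced_vs_unspliced(rng):
    gene, signal, probes = _spliced_setup(rng, intron_abundance=0.0)
    res = splicing_index(gene, signal, probes, "veg")
    assert res.label == "spliced"
    assert res.splicing_index < -1.5

    gene, signal, probes = _spliced_setup(rng, intron_abundance=0.7)
    res = splicing_index(gene, signal, probes, "veg")
    assert res.label == "unspliced_or_antisense_dominated"
    assert abs(res.splicing_index) < 0.5


def test_splicing_index_antisense_confound_reported(rng):
    """A silent gene under a covering antisense looks 'unspliced' on the
    sense strand; the strand-aware report exposes the antisense dominance."""
    seq = "".join(rng.choice(list("ACGT"), 4_000))
    genome = Genome([GenomeSequence("c", seq)])
    probes, _ = map_probes(design_tiling_probes(genome, 25), genome)
    gene = GeneModel(
        "g", "c", "+", 1_000, 2_400, exons=((1_000, 1_500), (1_900, 2_400))
    )
    cfg = SimConfig(
        seed=6, genome_length=4_000, noise_cv=0.05, affinity_sigma=0.3,
        conditions=("veg",),
        n_constitutive=0, n_meiotic_discrete=0, n_meiotic_utr3=0, n_fkh2_targets=0,
        n_new_antisense=0, n_internal_bidir=0, n_intron_spliced=0,
        n_intron_unspliced=0, n_twofold=0,
    )
    anti = TranscriptTruth(
        "t.as", "c", "-", 800, 2_600, "antisense_discrete", False, {"veg": 0.5},
        "g", covering=True,
    )
    matrix = simulate_intensities([anti], probes, cfg)
    signal = normalize_to_gdna(matrix, None, probes, [gene])
    res = splicing_index(gene, signal, probes, "veg")
    assert res.label == "unspliced_or_antisense_dominated"
    sense_avg = gene_strand_expression([gene], signal, probes, "veg").loc[
        "g", "sense_avg"
    ]
    assert res.antisense_avg > sense_avg + 1.5


def test_splicing_index_not_computable_without_intron_probes(toy_signal):
    _, probes, gene, signal = toy_signal  # single-exon gene
    res = splicing_index(gene, signal, probes, "s")
    assert res.label == "not_computable"
    assert res.splicing_index is None
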