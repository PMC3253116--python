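import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandtile.core_model import map_probes
from strandtile.segmentation import (
    SegmentationModel,
    optimal_rss,
    segment_genome,
    segment_signal,
)
from strandtile.normalization import normalize_to_gdna
from strandtile.synthetic_data import (
    design_tiling_probes,
    generate_genome_and_annotation,
    simulate_intensities,
)
from conftest import small_config


def rss_of(values: np.ndarray, cuts: list[int]) -> float:
    edges = [0, *cuts, len(values)]
    return sum(
        float(((values[a:b] - values[a:b].mean()) ** 2).sum())
        for a, b in zip(edges, edges[1:])
    )


def enumerate_min_rss(values: np.ndarray, k: int, min_probes: int = 1) -> float:
    """Brute-force minimum RSS over every placement of k-1 boundaries."""
    n = len(values)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = [0, *cuts, n]
        if any(b - a < min_probes for a, b in zip(edges, edges[1:])):
            continue
        best = min(best, rss_of(values, list(cuts)))
    return best


def test_constant_vector_single_segment():
    assert segment_signal(np.full(80, 3.7)) == []


def test_clean_step_found_exactly():
    values = np.concatenate([np.zeros(50), np.full(50, 5.0)])
    assert segment_signal(values) == [50]


def test_nonfinite_rejected_and_short_vector_single_segment():
    with pytest.raises(ValueError, match="finite"):
        segment_signal(np.array([1.0, np.nan, 2.0]))
    assert segment_signal(np.array([1.0, 9.0])) == []  # below min_probes


def test_dp_matches_exhaustive_enumeration(rng):
    """DP-optimal RSS equals brute force for all k on small random vectors."""
    for _ in range(30):
        n = int(rng.integers(6, 21))
        values = rng.normal(size=n) + rng.choice([0, 3], size=n)
        dp_rss = optimal_rss(values, max_k=4, min_probes=1)
        for k in range(1, 5):
            if k > n:
                continue
            assert dp_rss[k - 1] == pytest.approx(
                enumerate_min_rss(values, k), abs=1e-9
            )


@given(
    st.lists(
        st.floats(-5, 5, allow_nan=False, allow_infinity=False),
        min_size=4,
        max_size=40,
    )
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_optimal_rss_monotone_in_k_and_boundaries_tile(values):
    """More segments never fit worse, and returned cuts always tile the
    vector into min_probes-respecting pieces."""
    v = np.asarray(values)
    rss = optimal_rss(v, max_k=min(5, len(v)), min_probes=1)
    finite = rss[np.isfinite(rss)]
    assert all(a >= b - 1e-8 for a, b in zip(finite, finite[1:]))
    cuts = segment_signal(v)
    edges = [0, *cuts, len(v)]
    assert edges == sorted(set(edges))
    assert all(b - a >= SegmentationModel().min_probes for a, b in zip(edges, edges[1:]))


def test_min_probes_constraint_respected(rng):
    values = rng.normal(size=40)
    values[17:] += 6.0
    model = SegmentationModel(min_probes=5)
    cuts = segment_signal(values, model)
    edges = [0, *cuts, len(values)]
    assert all(b - a >= 5 for a, b in zip(edges, edges[1:]))


def test_returned_boundaries_locally_optimal(rng):
    """Perturbing any single boundary by +-1 never lowers the RSS."""
    values = np.concatenate(
        [rng.normal(0, 0.1, 40), rng.normal(4, 0.1, 30), rng.normal(1, 0.1, 50)]
    )
    cuts = segment_signal(values)
    base = rss_of(values, cuts)
    for i, c in enumerate(cuts):
        for d in (-1, 1):
            perturbed = sorted(set(cuts[:i] + [c + d] + cuts[i + 1 :]))
            if len(perturbed) != len(cuts):
                continue
            assert rss_of(values, perturbed) >= base - 1e-9


def test_pure_noise_rarely_split(rng):
    k1 = sum(segment_signal(rng.normal(size=100)) == [] for _ in range(40))
    assert k1 >= 38  # >= 95%


def test_boundary_recovery_under_noise(rng):
    """Two-level signals: boundaries within +-2 probes across noise levels."""
    for sd in (0.0, 0.1, 0.2):
        hits = 0
        for _ in range(30):
            values = np.concatenate([np.zeros(60), np.full(40, 3.0)])
            values += rng.normal(0, sd, size=100)
            cuts = segment_signal(values)
            hits += len(cuts) == 1 and abs(cuts[0] - 60) <= 2
        assert hits >= 28


def test_chunked_segmentation_still_finds_step(rng):
    model = SegmentationModel(chunk_size=1_500, chunk_overlap=200)
    values = rng.normal(0, 0.1, 4_000)
    values[2_345:] += 4.0
    cuts = segment_signal(values, model)
    assert any(abs(c - 2_345) <= 2 for c in cuts)
    assert len(cuts) <= 3


def test_segment_genome_tiles_probes_and_means_recheck(small_run):
    probes = small_run.probes
    signal = small_run.signal
    for (chrom, strand) in probes.keys():
        plist = probes.probes_for(chrom, strand)
        segs = [
            s
            for s in small_run.segments["veg"]
            if s.chrom == chrom and s.strand == strand
        ]
        segs.sort(key=lambda s: s.first_probe_index)
        # exact tiling of the probe vector
        assert segs[0].first_probe_index == 0
        assert segs[-1].last_probe_index == len(plist) - 1
        for a, b in zip(segs, segs[1:]):
            assert b.first_probe_index == a.last_probe_index + 1
        # stored means equal the mean over member probes
        col = signal.values["veg"]
        for s in segs:
            members = plist[s.first_probe_index : s.last_probe_index + 1]
            recomputed = col.loc[[p.probe_id for p in members]].mean()
            assert s.mean_intensity == pytest.approx(recomputed, abs=1e-9)


def test_segment_genome_recovers_planted_transcript_edges(rng):
    cfg = small_config(
        seed=31,
        genome_length=20_000,
        n_constitutive=2,
        n_meiotic_discrete=1,
        n_meiotic_utr3=0,
        n_fkh2_targets=1,
        n_new_antisense=0,
        n_internal_bidir=0,
        n_intron_spliced=0,
        n_intron_unspliced=0,
        n_twofold=0,
        noise_cv=0.1,
    )
    truth = generate_genome_and_annotation(cfg)
    probes, _ = map_probes(design_tiling_probes(truth.genome, cfg.probe_step), truth.genome)
    matrix = simulate_intensities(truth, probes, cfg)
    signal = normalize_to_gdna(matrix, None, probes, truth.genes)
    segs = segment_genome(signal, probes, sample="veg")
    tol = 2 * cfg.probe_step + 25
    for t in truth.transcripts:
        if t.abundance["veg"] < 0.2:
            continue
        starts = [s.genomic_start for s in segs if s.strand == t.strand]
        ends = [s.genomic_end for s in segs if s.strand == t.strand]
        assert min(abs(s - t.start) for s in starts) <= tol
        assert min(abs(e - t.end) for e in ends) <= tol
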