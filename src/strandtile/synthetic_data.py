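"""Synthetic genomes, annotations, probe designs and intensity matrices.

The generator emulates the transcript architectures the analysis is built
for, on a toy genome small enough to segment exactly:

* constitutively expressed mRNAs (the background cohort);
* mid-meiotic genes that are sense-silent in vegetative cells but covered by
  a long antisense RNA — either a discrete transcription unit (crp79/spo4
  style) or a multi-kb 3'UTR extension of a convergent opposite-strand
  neighbor (spo6/mug28 style) — with sense induction and antisense decrease
  through a meiotic time course;
* a flagged subset of the meiotic genes derepressed in a fkh2 mei4 double
  deletion;
* non-meiotic genes that gain a new covering antisense RNA at 6 h of
  meiosis, with a forkhead motif (GTAAAYA) planted upstream of the antisense
  start;
* genes with an internal bidirectional promoter (ACGCTC hexamer planted at
  the internal start) producing a 5'-truncated sense RNA plus a divergent
  antisense RNA;
* intron-containing genes in spliced and unspliced states;
* genes with an exact two-fold sense change between conditions, for
  fold-change recovery checks.

Signal model: probe affinities a_p are lognormal and multiplicative;
background is nonspecific hybridization subject to the same probe effect
(plus an optional affinity-free optical term, off by default), and noise is
multiplicative lognormal with unit mean.  This is the regime in which
ratio-to-gDNA normalization is exactly correct, which makes its target
well-defined and testable.  With the optical term at zero, a transcript at
abundance A lands at log2(1 + A/background_level) after normalization, so
default abundances put expressed levels in the ~0.5-5 range where the 0.5
and 1.0 thresholds used downstream are meaningful.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    Genome,
    GenomeSequence,
    GeneModel,
    IntensityMatrix,
    PROBE_LENGTH,
    ProbeMap,
    SampleInfo,
    reverse_complement,
)

CONDITIONS = ("veg", "mei4h", "mei6h", "fkh2_mei4")

FORKHEAD_MOTIF = "GTAAAYA"
INTERNAL_PROMOTER_HEXAMER = "ACGCTC"

# abundance programs, linear units (normalized level ~ log2(1 + A/bg))
MEIOTIC_SENSE = {"veg": 0.0, "mei4h": 0.4, "mei6h": 1.2, "fkh2_mei4": 0.0}
FKH2_DEREPRESSED_SENSE = {"veg": 0.0, "mei4h": 0.4, "mei6h": 1.2, "fkh2_mei4": 0.6}
MEIOTIC_ANTISENSE = {"veg": 0.35, "mei4h": 0.15, "mei6h": 0.05, "fkh2_mei4": 0.35}
NEW_ANTISENSE = {"veg": 0.05, "mei4h": 0.1, "mei6h": 0.5, "fkh2_mei4": 0.05}
TRUNCATED_SENSE = {c: 0.5 for c in CONDITIONS}
INTERNAL_ANTISENSE = {c: 0.3 for c in CONDITIONS}
INTRON_GENE_SENSE = {c: 0.7 for c in CONDITIONS}
# host sense drops as the new antisense appears (antisense-mediated repression)
NEW_ANTISENSE_HOST_SENSE = {"veg": 0.5, "mei4h": 0.4, "mei6h": 0.15, "fkh2_mei4": 0.5}
TWOFOLD_SENSE = {"veg": 2.0, "mei4h": 2.0, "mei6h": 4.0, "fkh2_mei4": 2.0}


@dataclass
class SimConfig:
    seed: int = 0
    structure_seed: int | None = None  # None -> tied to seed
    genome_length: int = 120_000
    chrom_id: str = "chr_sim"
    probe_step: int = 25
    affinity_sigma: float = 0.5
    background_level: float = 0.1
    optical_background: float = 0.0
    noise_cv: float = 0.2
    gdna_level: float = 1.0
    n_constitutive: int = 10
    n_meiotic_discrete: int = 4
    n_meiotic_utr3: int = 4
    n_fkh2_targets: int = 4
    n_new_antisense: int = 4
    n_internal_bidir: int = 2
    n_intron_spliced: int = 2
    n_intron_unspliced: int = 2
    n_twofold: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    antisense_motif_fraction: float = 1.0
    gap: int = 600

    def __post_init__(self):
        for name in (
            "genome_length",
            "probe_step",
            "affinity_sigma",
            "background_level",
            "noise_cv",
            "gdna_level",
            "gap",
        ):
            if getattr(self, name) < 0 or (
                name in ("genome_length", "probe_step", "gdna_level")
                and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.background_level <= 0 and self.optical_background <= 0:
            raise ValueError("some background term must be positive")
        n_meiotic = self.n_meiotic_discrete + self.n_meiotic_utr3
        if self.n_fkh2_targets > n_meiotic:
            raise ValueError("n_fkh2_targets exceeds the number of meiotic genes")
        if not 0 <= self.antisense_motif_fraction <= 1:
            raise ValueError("antisense_motif_fraction must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass
class TranscriptTruth:
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tclass: str  # sense_mRNA / antisense_discrete / antisense_utr3_extension /
    #              truncated_sense / divergent_internal_antisense / noncoding
    spliced: bool
    abundance: dict[str, float]
    parent_gene: str | None = None
    covering: bool = False
    blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError(f"{self.transcript_id}: negative abundance")
        if not self.blocks:
            object.__setattr__(self, "blocks", ((self.start, self.end),))

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GroundTruth:
    genome: Genome
    genes: list[GeneModel]
    transcripts: list[TranscriptTruth]
    gene_table: pd.DataFrame  # gene_id, architecture, flags
    motifs: list[dict]
    config: SimConfig

    def genes_by_architecture(self, *archs: str) -> list[str]:
        t = self.gene_table
        return list(t.index[t["architecture"].isin(archs)])

    def write(self, out_dir: str | Path) -> None:
        from . import io as stio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stio.write_genome_fasta(self.genome, out_dir / "genome.fasta")
        stio.write_gff3(self.genes, out_dir / "annotation.gff3")
        pd.DataFrame(
            [
                {
                    "transcript_id": t.transcript_id,
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "start": t.start,
                    "end": t.end,
                    "class": t.tclass,
                    "spliced": t.spliced,
                    "parent_gene": t.parent_gene,
                    "covering": t.covering,
                    **{f"abundance_{c}": t.abundance.get(c, 0.0) for c in self.config.conditions},
                }
                for t in self.transcripts
            ]
        ).to_csv(out_dir / "transcripts_truth.tsv", sep="\t", index=False)
        self.gene_table.to_csv(out_dir / "genes_truth.tsv", sep="\t")
        pd.DataFrame(self.motifs).to_csv(out_dir / "motifs_truth.tsv", sep="\t", index=False)
        (out_dir / "sim_config.json").write_text(self.config.to_json())


def expected_normalized_level(abundance: float, config: SimConfig) -> float:
    """Expected background-anchored log2 level of a transcript at this abundance.

    Exact when ``optical_background`` is zero (the default signal model).
    """
    bg = config.background_level
    g = config.gdna_level
    return float(
        np.log2((abundance + bg) / (g + bg)) - np.log2(bg / (g + bg))
    )


# ------------------------------------------------------------ genome build

def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_string(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _plant(seq: np.ndarray, pos: int, motif: str, strand: str) -> None:
    """Write a concrete motif instance into the genome array on a strand."""
    if strand == "-":
        motif = reverse_complement(motif)
    for i, b in enumerate(motif):
        seq[pos + i] = _BASE_INDEX[b]


def generate_genome_and_annotation(config: SimConfig) -> GroundTruth:
    """Build genome, gene models and transcript truth from a config.

    Fully deterministic under (seed, structure_seed); the genome and truth
    depend only on ``structure_seed`` (which defaults to ``seed``).
    """
    rng = np.random.default_rng(
        config.seed if config.structure_seed is None else config.structure_seed
    )
    gap = config.gap

    archs: list[str] = (
        ["constitutive"] * config.n_constitutive
        + ["meiotic_discrete"] * config.n_meiotic_discrete
        + ["meiotic_utr3"] * config.n_meiotic_utr3
        + ["new_antisense"] * config.n_new_antisense
        + ["internal_bidir"] * config.n_internal_bidir
        + ["intron_spliced"] * config.n_intron_spliced
        + ["intron_unspliced"] * config.n_intron_unspliced
        + ["twofold"] * config.n_twofold
    )
    order = rng.permutation(len(archs))
    archs = [archs[i] for i in order]

    slot_len = {
        "constitutive": gap + 1400,
        "meiotic_discrete": gap + 1400,
        "meiotic_utr3": gap + 1200 + gap + 1200,
        "new_antisense": gap + 1400,
        "internal_bidir": gap + 2000,
        "intron_spliced": gap + 1400,
        "intron_unspliced": gap + 1400,
        "twofold": gap + 1400,
    }
    required = sum(slot_len[a] for a in archs) + gap
    if config.genome_length < required:
        raise ValueError(
            f"genome_length={config.genome_length} too short for the requested "
            f"architectures (need >= {required} nt at gap={gap})"
        )

    seq = _random_dna(rng, config.genome_length)
    chrom = config.chrom_id
    genes: list[GeneModel] = []
    transcripts: list[TranscriptTruth] = []
    gene_rows: list[dict] = []
    motifs: list[dict] = []

    # fkh2-derepressed subset: first n_fkh2_targets meiotic genes in layout order
    n_meiotic_seen = 0
    antisense_like: list[TranscriptTruth] = []  # candidates for motif planting
    cursor = 0
    gi = 0

    def new_gene_id() -> str:
        nonlocal gi
        gi += 1
        return f"g{gi:03d}"

    def add_gene(gene: GeneModel, architecture: str, **flags) -> None:
        genes.append(gene)
        gene_rows.append(
            {"gene_id": gene.gene_id, "architecture": architecture, **flags}
        )

    for arch in archs:
        cursor += gap
        strand = "+" if rng.random() < 0.5 else "-"
        opposite = "-" if strand == "+" else "+"

        if arch in ("constitutive", "twofold"):
            gid = new_gene_id()
            s, e = cursor, cursor + 1400
            gene = GeneModel(gid, chrom, strand, s, e)
            if arch == "constitutive":
                level = float(rng.lognormal(np.log(0.8), 0.5))
                program = {c: level for c in config.conditions}
            else:
                program = {c: TWOFOLD_SENSE.get(c, 2.0) for c in config.conditions}
            add_gene(gene, arch, meiotic=False, fkh2_target=False)
            transcripts.append(
                TranscriptTruth(
                    f"{gid}.sense", chrom, strand, s, e, "sense_mRNA", False, program, gid
                )
            )
            cursor = e

        elif arch == "meiotic_discrete":
            gid = new_gene_id()
            s, e = cursor, cursor + 1400
            gene = GeneModel(gid, chrom, strand, s, e)
            n_meiotic_seen += 1
            is_fkh2 = n_meiotic_seen <= config.n_fkh2_targets
            sense_prog = FKH2_DEREPRESSED_SENSE if is_fkh2 else MEIOTIC_SENSE
            add_gene(gene, arch, meiotic=True, fkh2_target=is_fkh2)
            transcripts.append(
                TranscriptTruth(
                    f"{gid}.sense", chrom, strand, s, e, "sense_mRNA", False,
                    {c: sense_prog.get(c, 0.0) for c in config.conditions}, gid,
                )
            )
            anti = TranscriptTruth(
                f"{gid}.as", chrom, opposite, s - 150, e + 150,
                "antisense_discrete", False,
                {c: MEIOTIC_ANTISENSE.get(c, 0.0) for c in config.conditions},
                gid, covering=True,
            )
            transcripts.append(anti)
            antisense_like.append(anti)
            # forkhead motif upstream of the meiotic sense promoter
            _plant_forkhead(seq, gene.tss, strand, rng, motifs, gid, "meiotic_promoter")
            cursor = e

        elif arch == "meiotic_utr3":
            pid_, qid = new_gene_id(), new_gene_id()
            n_meiotic_seen += 1
            is_fkh2 = n_meiotic_seen <= config.n_fkh2_targets
            sense_prog = FKH2_DEREPRESSED_SENSE if is_fkh2 else MEIOTIC_SENSE
            if strand == "+":
                # P(+) then convergent neighbor Q(-) to the right; Q's 3'UTR
                # extends leftwards over P's entire CDS
                ps, pe = cursor, cursor + 1200
                qs, qe = pe + gap, pe + gap + 1200
                anti_iv = (ps - 150, qe)
            else:
                # mirrored: Q(+) to the left, 3'UTR extends rightwards over P(-)
                qs, qe = cursor, cursor + 1200
                ps, pe = qe + gap, qe + gap + 1200
                anti_iv = (qs, pe + 150)
            gene_p = GeneModel(pid_, chrom, strand, ps, pe)
            gene_q = GeneModel(
                qid, chrom, opposite, qs, qe,
                utr3_end=anti_iv[0] if strand == "+" else anti_iv[1],
            )
            add_gene(gene_p, arch, meiotic=True, fkh2_target=is_fkh2)
            add_gene(gene_q, "utr3_neighbor", meiotic=False, fkh2_target=False)
            transcripts.append(
                TranscriptTruth(
                    f"{pid_}.sense", chrom, strand, ps, pe, "sense_mRNA", False,
                    {c: sense_prog.get(c, 0.0) for c in config.conditions}, pid_,
                )
            )
            anti = TranscriptTruth(
                f"{pid_}.as_utr3", chrom, opposite, anti_iv[0], anti_iv[1],
                "antisense_utr3_extension", False,
                {c: MEIOTIC_ANTISENSE.get(c, 0.0) for c in config.conditions},
                pid_, covering=True,
            )
            transcripts.append(anti)
            antisense_like.append(anti)
            _plant_forkhead(seq, gene_p.tss, strand, rng, motifs, pid_, "meiotic_promoter")
            cursor = max(pe, qe)

        elif arch == "new_antisense":
            gid = new_gene_id()
            s, e = cursor, cursor + 1400
            gene = GeneModel(gid, chrom, strand, s, e)
            add_gene(gene, arch, meiotic=False, fkh2_target=False)
            transcripts.append(
                TranscriptTruth(
                    f"{gid}.sense", chrom, strand, s, e, "sense_mRNA", False,
                    {c: NEW_ANTISENSE_HOST_SENSE.get(c, 0.5) for c in config.conditions},
                    gid,
                )
            )
            anti = TranscriptTruth(
                f"{gid}.as_new", chrom, opposite, s - 150, e + 150,
                "antisense_discrete", False,
                {c: NEW_ANTISENSE.get(c, 0.0) for c in config.conditions},
                gid, covering=True,
            )
            transcripts.append(anti)
            antisense_like.append(anti)
            cursor = e

        elif arch == "internal_bidir":
            gid = new_gene_id()
            s, e = cursor, cursor + 2000
            mid = s + 1000
            gene = GeneModel(gid, chrom, strand, s, e)
            add_gene(gene, arch, meiotic=True, fkh2_target=False)
            # 5'-truncated sense RNA from the internal start to the 3' end
            if strand == "+":
                trunc_iv, anti_iv = (mid, e + 100), (s - 300, mid)
            else:
                trunc_iv, anti_iv = (s - 100, mid), (mid, e + 300)
            transcripts.append(
                TranscriptTruth(
                    f"{gid}.trunc", chrom, strand, trunc_iv[0], trunc_iv[1],
                    "truncated_sense", False,
                    {c: TRUNCATED_SENSE.get(c, 0.5) for c in config.conditions}, gid,
                )
            )
            transcripts.append(
                TranscriptTruth(
                    f"{gid}.int_as", chrom, opposite, anti_iv[0], anti_iv[1],
                    "divergent_internal_antisense", False,
                    {c: INTERNAL_ANTISENSE.get(c, 0.3) for c in config.conditions}, gid,
                )
            )
            # full-length sense from the meiotic promoter at 6 h
            transcripts.append(
                TranscriptTruth(
                    f"{gid}.sense", chrom, strand, s, e, "sense_mRNA", False,
                    {c: (1.0 if c == "mei6h" else 0.0) for c in config.conditions}, gid,
                )
            )
            _plant(seq, mid - 3, INTERNAL_PROMOTER_HEXAMER, "+")
            motifs.append(
                {
                    "motif": INTERNAL_PROMOTER_HEXAMER,
                    "chrom": chrom,
                    "strand": "+",
                    "start": mid - 3,
                    "gene_id": gid,
                    "planted_for": "internal_promoter",
                }
            )
            _plant_forkhead(seq, gene.tss, strand, rng, motifs, gid, "meiotic_promoter")
            cursor = e

        elif arch in ("intron_spliced", "intron_unspliced"):
            gid = new_gene_id()
            s, e = cursor, cursor + 1400
            exons = ((s, s + 500), (s + 800, e))
            gene = GeneModel(gid, chrom, strand, s, e, exons=exons)
            add_gene(gene, arch, meiotic=False, fkh2_target=False)
            spliced = arch == "intron_spliced"
            transcripts.append(
                TranscriptTruth(
                    f"{gid}.sense", chrom, strand, s, e, "sense_mRNA", spliced,
                    {c: INTRON_GENE_SENSE.get(c, 0.7) for c in config.conditions},
                    gid, blocks=exons if spliced else (),
                )
            )
            cursor = e

        else:  # pragma: no cover
            raise AssertionError(arch)

    # plant forkhead motifs upstream of an exact fraction of antisense starts
    k = int(round(config.antisense_motif_fraction * len(antisense_like)))
    chosen = rng.permutation(len(antisense_like))[:k]
    for idx in sorted(chosen):
        t = antisense_like[idx]
        _plant_forkhead(
            seq, t.five_prime, t.strand, rng, motifs, t.parent_gene, "antisense_start"
        )

    for m in motifs:
        m["chrom"] = chrom

    gene_table = pd.DataFrame(
        gene_rows, columns=["gene_id", "architecture", "meiotic", "fkh2_target"]
    ).set_index("gene_id")
    has_motif = {m["gene_id"] for m in motifs if m["planted_for"] == "antisense_start"}
    gene_table["antisense_motif_planted"] = [
        g in has_motif for g in gene_table.index
    ]
    genome = Genome([GenomeSequence(chrom, _to_string(seq))])
    return GroundTruth(genome, genes, transcripts, gene_table, motifs, config)


def _plant_forkhead(seq, tss, strand, rng, motifs, gene_id, planted_for) -> None:
    """Plant a concrete GTAAAYA instance 20-150 nt upstream of a 5' start."""
    offset = int(rng.integers(20, 151))
    motif = "GTAAA" + ("C" if rng.random() < 0.5 else "T") + "A"
    if strand == "+":
        pos = tss - offset - len(motif)
    else:
        pos = tss + offset
    if pos < 0 or pos + len(motif) > len(seq):
        return
    _plant(seq, pos, motif, strand)
    motifs.append(
        {
            "motif": FORKHEAD_MOTIF,
            "chrom": None,  # filled by caller context (single-chrom generator)
            "strand": strand,
            "start": pos,
            "gene_id": gene_id,
            "planted_for": planted_for,
        }
    )


# ------------------------------------------------------------- probe design

def design_tiling_probes(genome: Genome, step: int) -> list[str]:
    """25-nt probes every ``step`` nt on both strands of every chromosome."""
    if step < 1:
        raise ValueError("step must be >= 1")
    out: list[str] = []
    for chrom in genome:
        L = len(chrom)
        if L < PROBE_LENGTH:
            warnings.warn(f"chromosome {chrom.chrom_id} shorter than a probe")
            continue
        for p in range(0, L - PROBE_LENGTH + 1, step):
            window = chrom.sequence[p : p + PROBE_LENGTH]
            out.append(window)
            out.append(reverse_complement(window))
    return out


# --------------------------------------------------------------- intensities

def probe_ids_sorted(probes: ProbeMap) -> list[str]:
    return sorted({p.probe_id for p in probes})


def probe_affinities(probes: ProbeMap, config: SimConfig) -> pd.Series:
    """The per-probe lognormal affinities used by :func:`simulate_intensities`.

    Drawn from a dedicated child stream of ``config.seed`` so that metrics
    code can recover exactly the affinities a simulation used.
    """
    ids = probe_ids_sorted(probes)
    rng = np.random.default_rng([config.seed, 0])
    return pd.Series(
        rng.lognormal(0.0, config.affinity_sigma, size=len(ids)), index=ids
    )


def probe_coverage(
    transcripts: list[TranscriptTruth],
    probes: ProbeMap,
    conditions: tuple[str, ...],
) -> dict[str, pd.Series]:
    """Per condition, summed abundance of same-strand transcripts overlapping
    each probe's footprint by >= 1 nt (no fractional weighting)."""
    ids = probe_ids_sorted(probes)
    id_index = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    coverage = {c: np.zeros(n) for c in conditions}
    by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key in probes.keys():
        plist = probes.probes_for(*key, unique_only=False)
        starts = np.array([p.start for p in plist])
        rows = np.array([id_index[p.probe_id] for p in plist])
        by_key[key] = (starts, rows)
    for t in transcripts:
        key = (t.chrom, t.strand)
        if key not in by_key:
            continue
        starts, rows = by_key[key]
        for bs, be in t.blocks:
            lo = np.searchsorted(starts, bs - PROBE_LENGTH + 1, side="left")
            hi = np.searchsorted(starts, be, side="left")
            if hi <= lo:
                continue
            sel = rows[lo:hi]
            for c in conditions:
                a = t.abundance.get(c, 0.0)
                if a:
                    np.add.at(coverage[c], sel, a)
    return {c: pd.Series(v, index=ids) for c, v in coverage.items()}


def simulate_intensities(
    truth: list[TranscriptTruth] | GroundTruth,
    probes: ProbeMap,
    config: SimConfig,
) -> IntensityMatrix:
    """Raw linear intensities for every RNA condition plus a gDNA channel.

    Per probe p and condition c:
    raw = (a_p * (A_pc + bg_hyb) + bg_opt) * lognormal_noise, where A_pc sums
    the abundances of same-strand transcripts overlapping p's footprint by
    >= 1 nt, a_p ~ lognormal(0, affinity_sigma) once per probe, and the noise
    has unit mean and coefficient of variation ``noise_cv``.
    The gDNA channel uses A = gdna_level for every probe.
    """
    transcripts = truth.transcripts if isinstance(truth, GroundTruth) else truth
    rng = np.random.default_rng([config.seed, 1])  # noise stream

    probe_ids = probe_ids_sorted(probes)
    n = len(probe_ids)
    affinities = probe_affinities(probes, config).to_numpy()
    coverage = {
        c: v.to_numpy()
        for c, v in probe_coverage(transcripts, probes, config.conditions).items()
    }

    sigma = np.sqrt(np.log1p(config.noise_cv**2))

    def noisy(expected: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return expected.copy()
        return expected * rng.lognormal(-0.5 * sigma**2, sigma, size=n)

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleInfo] = []
    for c in config.conditions:
        expected = (
            affinities * (coverage[c] + config.background_level)
            + config.optical_background
        )
        columns[c] = noisy(expected)
        samples.append(SampleInfo(c, c, "RNA"))
    expected_g = affinities * config.gdna_level + config.optical_background
    columns["gdna"] = noisy(expected_g)
    samples.append(SampleInfo("gdna", "gdna", "gDNA"))

    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    return IntensityMatrix(values, samples)


# ------------------------------------------------ gene-level delta generator

def simulate_expression_deltas(
    n_genes: int,
    rho: float,
    seed: int,
    delta_scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two per-gene (sense_avg, antisense_avg) tables with a planted Pearson
    correlation ``rho`` between the sense and antisense deltas.

    Baselines mimic the scale of normalized tiling data (sense ~ N(3, 1),
    antisense ~ N(0.3, 0.5)); deltas are bivariate normal with unit marginal
    scale times ``delta_scale``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"gene_{i:05d}" for i in range(n_genes)], name="gene_id")
    base = pd.DataFrame(
        {
            "sense_avg": rng.normal(3.0, 1.0, n_genes),
            "antisense_avg": rng.normal(0.3, 0.5, n_genes),
        },
        index=genes,
    )
    cov = delta_scale**2 * np.array([[1.0, rho], [rho, 1.0]])
    deltas = rng.multivariate_normal([0.0, 0.0], cov, size=n_genes)
    after = base + deltas
    after.columns = base.columns
    return base, after


# -------------------------------------------------- expectation conveniences

def expected_gene_levels(truth: GroundTruth) -> pd.DataFrame:
    """Noise-free expected per-gene sense/antisense normalized levels.

    Averages log2(1 + A/bg) over probe-pitch positions across each gene's
    CDS; exact up to probe-edge effects when optical background is zero.
    Columns: <condition>_sense, <condition>_antisense.
    """
    cfg = truth.config
    rows = {}
    for gene in truth.genes:
        pos = np.arange(gene.cds_start, gene.cds_end - PROBE_LENGTH + 1, cfg.probe_step)
        rec = {}
        for strand_label, strand in (("sense", gene.strand), ("antisense", "+" if gene.strand == "-" else "-")):
            cover = {c: np.zeros(len(pos)) for c in cfg.conditions}
            for t in truth.transcripts:
                if t.chrom != gene.chrom or t.strand != strand:
                    continue
                for bs, be in t.blocks:
                    sel = (pos + PROBE_LENGTH > bs) & (pos < be)
                    for c in cfg.conditions:
                        cover[c][sel] += t.abundance.get(c, 0.0)
            for c in cfg.conditions:
                levels = [expected_normalized_level(a, cfg) for a in cover[c]]
                rec[f"{c}_{strand_label}"] = float(np.mean(levels)) if levels else np.nan
        rows[gene.gene_id] = rec
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df
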