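"""Seeded synthetic-data generator for RRBS development and validation.

Emulates the features of a mammalian methylome experiment that the analysis
chain depends on: a CpG-depleted background genome with embedded CpG-island
segments, bimodal per-CpG methylation (islands low, background high),
directional paired-end bisulfite reads starting at restriction cut sites,
incomplete conversion, sequencing error, the end-repair fill-in artifact
(always-unmethylated filled bases read through the reverse read's 5' end)
and an unmethylated lambda-like spike-in contig for conversion-rate
estimation.

What it does NOT emulate: PCR duplication and amplification bias, indels and
adapter read-through, base-caller error profiles, methylation-sensitive or
partial digestion.  All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .elements import GeneModel, GenomicInterval
from .enzymes import CONTIG_END, Enzyme, Fragment, SizeWindow
from .coverage import ReadLayout, PE50

LAMBDA_CONTIG = "lambda_spike"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A", b"N": b"N"}
_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _k, _v in _COMP.items():
    _COMP_TABLE[_k[0]] = _v[0]
    _COMP_TABLE[_k[0] + 32] = _v[0]


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[arr][::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated double-enzyme RRBS experiment.

    Defaults mirror the experimental design being modelled: PE50 layout,
    40-220 bp size selection, ~99.5% bisulfite conversion with an
    unmethylated lambda spike-in, bimodal methylation (island CpGs mostly
    unmethylated, background CpGs mostly methylated) and an end-repair
    fill-in artifact at fragment ends.
    """

    seed: int
    genome_length: int = 500_000
    background_gc: float = 0.40
    background_cpg_retention: float = 0.25  # background O/E CpG ratio
    n_cgis: int = 40
    cgi_length: int = 600
    cgi_gc: float = 0.65
    cgi_cpg_retention: float = 0.90
    n_genes: int = 30
    size_window: SizeWindow = field(default_factory=lambda: SizeWindow(40, 220))
    layout: ReadLayout = PE50
    target_depth: float = 20.0
    conversion_rate: float = 0.995
    error_rate: float = 0.001
    lambda_fraction: float = 0.05
    lambda_length: int = 48_500
    low_quality_fraction: float = 0.0
    base_quality: int = 35
    low_quality_value: int = 10

    def __post_init__(self):
        for name in (
            "background_gc",
            "background_cpg_retention",
            "cgi_gc",
            "cgi_cpg_retention",
            "conversion_rate",
            "error_rate",
            "lambda_fraction",
            "low_quality_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cgis * self.cgi_length > self.genome_length // 2:
            raise ValueError("requested CGIs exceed half the genome length")


# beta(a, b) parameters per element class for the methylome truth
DEFAULT_BETA_PARAMS = {
    "CGI": (2.0, 18.0),  # mean 0.1: islands mostly unmethylated
    "OTHER": (8.0, 2.0),  # mean 0.8: background mostly methylated
}


@dataclass
class MethylomeTruth:
    """Per-CpG methylation probability (+ strand C position keyed)."""

    probs: dict[str, dict[int, float]]
    beta_params: dict[str, tuple[float, float]]

    def get(self, contig: str, pos: int) -> float | None:
        return self.probs.get(contig, {}).get(pos)

    def prob_arrays(self, genome: Mapping[str, str]) -> dict[str, np.ndarray]:
        """Dense per-position array: truth prob at each CpG C position else 0."""
        out = {}
        for contig, seq in genome.items():
            arr = np.zeros(len(seq), dtype=np.float64)
            for pos, p in self.probs.get(contig, {}).items():
                arr[pos] = p
            out[contig] = arr
        return out


@dataclass
class ReadPair:
    name: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    # truth tags
    contig: str
    fragment_start: int
    fragment_end: int
    filled_end: int
    strand: str  # "top" / "bottom" original strand
    left_enzyme: str
    right_enzyme: str


def _random_sequence(
    rng: np.random.Generator, length: int, gc: float, cpg_retention: float
) -> np.ndarray:
    """iid sequence at a GC target with CpG depletion to a given retention.

    The initial GC is inflated to compensate for the G bases destroyed by
    depletion, so the realized GC lands near the request.
    """
    g0 = min(0.95, gc + (gc / 2) ** 2 * (1.0 - cpg_retention))
    p = np.array([(1 - g0) / 2, g0 / 2, g0 / 2, (1 - g0) / 2])
    arr = _BASES[rng.choice(4, size=length, p=p)].view(np.uint8).copy()
    if cpg_retention < 1.0 and length > 1:
        cg = np.where((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]
        drop = cg[rng.random(len(cg)) >= cpg_retention]
        at = np.frombuffer(b"AT", dtype=np.uint8)
        arr[drop + 1] = at[rng.integers(0, 2, size=len(drop))]
    return arr


def synthesize_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[GenomicInterval], list[GeneModel]]:
    """Background + embedded islands + lambda-like spike contig.

    Returns (genome, truth CGI intervals, gene models). Gene TSSs are placed
    at island centres (about half, mirroring real promoter-CGI association)
    and at random background positions; each gene has three exons so introns
    exist as an element class. Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.genome_length
    arr = _random_sequence(rng, n, config.background_gc, config.background_cpg_retention)

    # island placement: evenly partition the contig, jitter inside bins
    margin = 2 * config.cgi_length + 1000
    if config.n_cgis > 0 and n < config.n_cgis * (config.cgi_length + margin):
        raise ValueError("genome too short for requested CGI count/length")
    truth_cgis: list[GenomicInterval] = []
    if config.n_cgis:
        bin_size = n // config.n_cgis
        for i in range(config.n_cgis):
            lo = i * bin_size + 500
            hi = (i + 1) * bin_size - config.cgi_length - 500
            start = int(rng.integers(lo, max(lo + 1, hi)))
            island = _random_sequence(
                rng, config.cgi_length, config.cgi_gc, config.cgi_cpg_retention
            )
            arr[start : start + config.cgi_length] = island
            truth_cgis.append(
                GenomicInterval("chr1", start, start + config.cgi_length, ".", "CGI", f"truth_cgi_{i}")
            )

    genes: list[GeneModel] = []
    if config.n_genes:
        exon, intron = 200, 800
        span = 3 * exon + 2 * intron
        for i in range(config.n_genes):
            strand = "+" if rng.random() < 0.5 else "-"
            if i < len(truth_cgis) and i % 2 == 0:
                tss = (truth_cgis[i].start + truth_cgis[i].end) // 2
            else:
                tss = int(rng.integers(3000, n - 3000 - span))
            if strand == "+":
                first = tss
                exons = tuple(
                    (first + j * (exon + intron), first + j * (exon + intron) + exon)
                    for j in range(3)
                )
            else:
                last_end = tss + 1
                exons = tuple(
                    (last_end - span + j * (exon + intron),
                     last_end - span + j * (exon + intron) + exon)
                    for j in range(3)
                )
                exons = tuple((max(0, s), e) for s, e in exons if e > 0)
            if not exons or exons[-1][1] > n:
                continue
            genes.append(GeneModel(f"gene_{i}", "chr1", strand, tss, exons))

    lam = _random_sequence(rng, config.lambda_length, 0.5, 1.0)
    genome = {"chr1": array_to_seq(arr), LAMBDA_CONTIG: array_to_seq(lam)}
    return genome, truth_cgis, genes


def assign_methylome(
    genome: Mapping[str, str],
    elements: Sequence[GenomicInterval],
    beta_params: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> MethylomeTruth:
    """Draw per-CpG methylation probabilities from class beta distributions.

    CpGs inside a CGI interval use the CGI parameters, all others the OTHER
    (background) parameters; the lambda spike contig is exactly unmethylated.
    """
    params = dict(DEFAULT_BETA_PARAMS)
    if beta_params:
        params.update(beta_params)
    for cls, (a, b) in params.items():
        if a <= 0 or b <= 0:
            raise ValueError(f"invalid beta parameters for {cls}: ({a}, {b})")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    from .coverage import cpg_positions

    cpgs = cpg_positions(genome)
    probs: dict[str, dict[int, float]] = {}
    for contig, positions in cpgs.items():
        if contig == LAMBDA_CONTIG:
            probs[contig] = {int(p): 0.0 for p in positions}
            continue
        in_cgi = np.zeros(len(positions), dtype=bool)
        for el in elements:
            if el.element_class == "CGI" and el.contig == contig:
                lo, hi = np.searchsorted(positions, [el.start, el.end])
                in_cgi[lo:hi] = True
        draws = np.empty(len(positions))
        a, b = params["CGI"]
        draws[in_cgi] = rng.beta(a, b, size=int(in_cgi.sum()))
        a, b = params["OTHER"]
        draws[~in_cgi] = rng.beta(a, b, size=int((~in_cgi).sum()))
        probs[contig] = {int(p): float(v) for p, v in zip(positions, draws)}
    return MethylomeTruth(probs=probs, beta_params=params)


def perturb_methylome(
    truth: MethylomeTruth,
    regions: Sequence[GenomicInterval],
    beta_params: tuple[float, float],
    seed: int,
) -> MethylomeTruth:
    """Copy of ``truth`` with CpGs inside ``regions`` redrawn from a beta.

    Used to build a second sample whose methylome is identical outside the
    listed regions (a clean null) and shifted inside them (true DMRs).
    """
    a, b = beta_params
    if a <= 0 or b <= 0:
        raise ValueError("invalid beta parameters")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    probs = {contig: dict(d) for contig, d in truth.probs.items()}
    for region in regions:
        d = probs.get(region.contig)
        if not d:
            continue
        for pos in sorted(d):
            if region.start <= pos < region.end:
                d[pos] = float(rng.beta(a, b))
    return MethylomeTruth(probs=probs, beta_params=dict(truth.beta_params))


def simulate_dge_counts(
    gene_ids: Sequence[str],
    seed: int,
    library_size: int = 2_000_000,
    de_fraction: float = 0.1,
    de_fold: float = 4.0,
) -> tuple[list[tuple[str, int, int]], set[str]]:
    """Two-library digital tag counts with a known differential subset.

    Baseline expression is log-normal; each library is a multinomial draw of
    ``library_size`` tags.  A ``de_fraction`` of genes has its rate scaled by
    ``de_fold`` in library B.  Returns (gene, count A, count B) rows plus the
    set of truly differential gene ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    n = len(gene_ids)
    base = rng.lognormal(mean=3.0, sigma=1.2, size=n)
    de = rng.random(n) < de_fraction
    rate_a = base / base.sum()
    rate_b = base * np.where(de, de_fold, 1.0)
    rate_b = rate_b / rate_b.sum()
    counts_a = rng.multinomial(library_size, rate_a)
    counts_b = rng.multinomial(library_size, rate_b)
    rows = [(g, int(a), int(b)) for g, a, b in zip(gene_ids, counts_a, counts_b)]
    return rows, {g for g, flag in zip(gene_ids, de) if flag}


def _phred(qual_vals: np.ndarray) -> str:
    return (qual_vals + 33).astype(np.uint8).tobytes().decode("ascii")


def simulate_reads(
    genome: Mapping[str, str],
    truth: MethylomeTruth,
    fragments_selected: Sequence[Fragment],
    config: SimConfig,
    enzymes: Mapping[str, Enzyme] | None = None,
    stream: int = 0,
) -> list[ReadPair]:
    """Directional paired-end bisulfite reads from size-selected fragments.

    Per fragment, Poisson(target depth) molecules are sampled, each from the
    top or bottom original strand with equal probability.  Unmethylated
    cytosines on the molecule's strand convert C->T with probability equal to
    the conversion rate; methylated cytosines never convert (before
    sequencing error).  Per-molecule methylation state is Bernoulli(truth
    probability).  Fill-in bases (the right-end top-strand extension for top
    molecules, the left-end bottom-strand extension for bottom molecules,
    each of the boundary enzyme's overhang length) are always unmethylated —
    the end-repair artifact.  Lambda-contig fragments are down-sampled so
    spiked pairs make up about ``lambda_fraction`` of the output.
    """
    import warnings

    if not fragments_selected:
        warnings.warn("no fragments to simulate; empty read output")
        return []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303, stream]))
    arrays = {c: seq_to_array(s) for c, s in genome.items()}
    prob_arrays = truth.prob_arrays(genome)
    # bottom-strand CpG C sits at p+1; same per-CpG probability applies
    bottom_prob = {}
    for contig, arr in prob_arrays.items():
        b = np.zeros_like(arr)
        b[1:] = arr[:-1]
        bottom_prob[contig] = b

    genomic = [f for f in fragments_selected if f.contig != LAMBDA_CONTIG]
    lam = [f for f in fragments_selected if f.contig == LAMBDA_CONTIG]
    lam_depth = 0.0
    if lam and config.lambda_fraction > 0:
        expected_pairs = config.target_depth * max(1, len(genomic))
        lam_pairs = config.lambda_fraction / max(1e-9, 1 - config.lambda_fraction) * expected_pairs
        lam_depth = lam_pairs / len(lam)

    length = config.layout.read_length
    pairs: list[ReadPair] = []
    serial = 0
    for frag in fragments_selected:
        depth = lam_depth if frag.contig == LAMBDA_CONTIG else config.target_depth
        n_mol = int(rng.poisson(depth))
        if n_mol == 0:
            continue
        arr = arrays[frag.contig]
        seg = arr[frag.filled_start : frag.filled_end]
        flen = len(seg)
        p_top = prob_arrays[frag.contig][frag.filled_start : frag.filled_end].copy()
        p_bot = bottom_prob[frag.contig][frag.filled_start : frag.filled_end].copy()
        # fill-in artifact: forced-unmethylated windows
        fill_right = frag.filled_end - frag.end  # top-strand right-end fill
        left_ov = 0
        if enzymes is not None and frag.left_enzyme != CONTIG_END:
            left_ov = enzymes[frag.left_enzyme].overhang_len
        is_c = seg == ord("C")
        is_g = seg == ord("G")
        for _ in range(n_mol):
            top = rng.random() < 0.5
            if top:
                probs = p_top.copy()
                if fill_right:
                    probs[flen - fill_right :] = 0.0
                meth = rng.random(flen) < probs
                convert = is_c & ~meth & (rng.random(flen) < config.conversion_rate)
                mol = seg.copy()
                mol[convert] = ord("T")
                r1 = mol[:length].copy()
                r2 = revcomp_array(mol)[:length].copy()
            else:
                probs = p_bot.copy()
                if left_ov:
                    probs[:left_ov] = 0.0
                meth = rng.random(flen) < probs
                convert = is_g & ~meth & (rng.random(flen) < config.conversion_rate)
                proj = seg.copy()  # top-orientation projection of converted bottom strand
                proj[convert] = ord("A")
                bottom = revcomp_array(proj)
                r1 = bottom[:length].copy()
                r2 = proj[:length].copy()
            quals = []
            for r in (r1, r2):
                if config.error_rate > 0:
                    err = rng.random(len(r)) < config.error_rate
                    if err.any():
                        idx = np.where(err)[0]
                        r[idx] = _BASES[rng.integers(0, 4, size=len(idx))].view(np.uint8)
                q = np.full(len(r), config.base_quality, dtype=np.int64)
                if config.low_quality_fraction > 0:
                    low = rng.random(len(r)) < config.low_quality_fraction
                    q[low] = config.low_quality_value
                quals.append(q)
            name = f"sim_{frag.contig}_{frag.start}_{serial}"
            serial += 1
            pairs.append(
                ReadPair(
                    name=name,
                    r1_seq=array_to_seq(r1),
                    r1_qual=_phred(quals[0]),
                    r2_seq=array_to_seq(r2),
                    r2_qual=_phred(quals[1]),
                    contig=frag.contig,
                    fragment_start=frag.start,
                    fragment_end=frag.end,
                    filled_end=frag.filled_end,
                    strand="top" if top else "bottom",
                    left_enzyme=frag.left_enzyme,
                    right_enzyme=frag.right_enzyme,
                )
            )
    return pairs
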