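"""RRBS analysis core: read QC, three-letter bisulfite alignment, enzyme-end
filtering, fill-in masking, per-CpG methylation calling and conversion-rate
estimation from the lambda spike-in.

Alignment uses the classic "three-letter" scheme: two alignment-form
references are built (all C->T, and all G->A), the forward read is C->T
transformed and the reverse read handled through its reverse complement, and
a read pair is reported only when it has exactly one best-scoring
full-length ungapped placement across both forms.  The built-in mapper is
exact-k-mer-seeded and intended for simulated or small genomes; alignments
from an external aligner can be imported from SAM/BAM instead.

Calling pools both strands of a CpG into one dinucleotide record: reads from
the top-converted strand vote at the C (C = methylated, T = unmethylated),
reads from the bottom-converted strand vote at the G (G = methylated,
A = unmethylated); level = M / (M + U).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enzymes import CONTIG_END, CutSite, Enzyme
from .simulate import revcomp_array, seq_to_array

TOP, BOTTOM = "top", "bottom"


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    quality: str


@dataclass
class AlignedRead:
    read_id: str
    contig: str
    start: int  # genome coordinates, top strand
    end: int
    strand: str  # "top" / "bottom" converted original strand
    mate: str  # "fwd" / "rev"
    mismatches: int
    bases: np.ndarray  # original read bases projected to top-strand orientation
    mask_len: int = 0  # reverse reads only: 5'-end fill-in bases to ignore

    def masked_interval(self) -> tuple[int, int]:
        """Genome interval excluded from counting (empty when mask_len 0)."""
        if self.mask_len == 0:
            return (self.start, self.start)
        if self.strand == TOP:  # reverse read 5' end at the genome-right end
            return (self.end - self.mask_len, self.end)
        return (self.start, self.start + self.mask_len)


@dataclass
class AlignedPair:
    r_fwd: AlignedRead
    r_rev: AlignedRead
    strand: str
    contig: str
    score: int

    @property
    def left(self) -> int:
        return min(self.r_fwd.start, self.r_rev.start)

    @property
    def right(self) -> int:
        return max(self.r_fwd.end, self.r_rev.end)

    @property
    def reads(self) -> tuple[AlignedRead, AlignedRead]:
        return (self.r_fwd, self.r_rev)


@dataclass(frozen=True)
class CpGCall:
    contig: str
    position: int  # + strand C of the dinucleotide
    methylated: int
    unmethylated: int

    @property
    def depth(self) -> int:
        return self.methylated + self.unmethylated

    @property
    def level(self) -> float:
        return self.methylated / self.depth if self.depth else math.nan


def qc_filter(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    max_n_fraction: float = 0.30,
    max_low_quality_fraction: float = 0.10,
    min_quality: int = 20,
    phred_offset: int = 33,
) -> tuple[list[tuple[FastqRead, FastqRead]], dict]:
    """Drop low-quality read pairs.

    A read fails iff its N fraction exceeds ``max_n_fraction`` or the
    fraction of bases below ``min_quality`` exceeds
    ``max_low_quality_fraction`` (both strictly); a pair is dropped when
    either mate fails.
    """
    kept = []
    n_in = n_out = 0
    for r1, r2 in pairs:
        n_in += 1
        ok = True
        for r in (r1, r2):
            if len(r.sequence) != len(r.quality):
                raise ValueError(f"read {r.name}: sequence/quality length mismatch")
            if not r.sequence:
                ok = False
                continue
            n_frac = r.sequence.upper().count("N") / len(r.sequence)
            quals = np.frombuffer(r.quality.encode("ascii"), dtype=np.uint8) - phred_offset
            lowq_frac = float((quals < min_quality).mean())
            if n_frac > max_n_fraction or lowq_frac > max_low_quality_fraction:
                ok = False
        if ok:
            kept.append((r1, r2))
            n_out += 1
    return kept, {"pairs_in": n_in, "pairs_kept": n_out, "pairs_dropped": n_in - n_out}


_ENC = np.full(256, 4, dtype=np.int64)  # 4 = N / anything else
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i


def transform_ct(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == ord("C")] = ord("T")
    return out


def transform_ga(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == ord("G")] = ord("A")
    return out


class BisulfiteIndex:
    """k-mer seed index over the two alignment-form references."""

    def __init__(self, genome: Mapping[str, str], k: int = 20):
        self.k = k
        self.contigs = list(genome)
        self.lengths = {c: len(s) for c, s in genome.items()}
        self.forms: dict[str, dict[str, np.ndarray]] = {"CT": {}, "GA": {}}
        self.index: dict[str, dict[str, dict[int, list[int]]]] = {"CT": {}, "GA": {}}
        for contig, seq in genome.items():
            arr = seq_to_array(seq)
            for form, transform in (("CT", transform_ct), ("GA", transform_ga)):
                t = transform(arr)
                self.forms[form][contig] = t
                self.index[form][contig] = self._build(t)

    def _build(self, t: np.ndarray) -> dict[int, list[int]]:
        k = self.k
        n = len(t)
        table: dict[int, list[int]] = {}
        if n < k:
            return table
        codes = _ENC[t]
        valid = codes < 4
        win_valid = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        safe = np.where(valid, codes, 0)
        hashes = np.lib.stride_tricks.sliding_window_view(safe, k) @ powers
        for pos in np.where(win_valid)[0]:
            table.setdefault(int(hashes[pos]), []).append(int(pos))
        return table

    def candidates(self, read_t: np.ndarray, form: str) -> dict[str, set[int]]:
        """Candidate start positions per contig from up to three seeds."""
        k = self.k
        codes = _ENC[read_t]
        n = len(read_t)
        offsets = [o for o in (0, k, 2 * k) if o + k <= n]
        if not offsets and n >= k:
            offsets = [0]
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        out: dict[str, set[int]] = {}
        for contig in self.contigs:
            table = self.index[form][contig]
            cands = out.setdefault(contig, set())
            for off in offsets:
                window = codes[off : off + k]
                if (window >= 4).any():
                    continue
                h = int(window @ powers)
                for pos in table.get(h, ()):
                    start = pos - off
                    if 0 <= start and start + n <= self.lengths[contig]:
                        cands.add(start)
        return out

    def verify(
        self, read_t: np.ndarray, form: str, contig: str, start: int
    ) -> int:
        ref = self.forms[form][contig][start : start + len(read_t)]
        return int((ref != read_t).sum())


def _align_component(
    index: BisulfiteIndex, read_t: np.ndarray, form: str, max_mismatches: int
) -> list[tuple[str, int, int]]:
    hits = []
    for contig, starts in index.candidates(read_t, form).items():
        for start in starts:
            mm = index.verify(read_t, form, contig, start)
            if mm <= max_mismatches:
                hits.append((contig, start, mm))
    return hits


def bisulfite_map(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    genome: Mapping[str, str],
    max_mismatches: int = 2,
    max_insert: int = 1000,
    index: BisulfiteIndex | None = None,
) -> list[AlignedPair]:
    """Align pairs with the built-in three-letter mapper.

    A pair is reported only when it has exactly one best-scoring (total
    mismatches) consistent placement across both alignment forms; ties and
    multi-mappers are discarded, so the output is independent of input
    order.
    """
    if index is None:
        index = BisulfiteIndex(genome)
    out: list[AlignedPair] = []
    for r1, r2 in pairs:
        a1 = seq_to_array(r1.sequence)
        a2 = seq_to_array(r2.sequence)
        placements: list[tuple[int, str, str, int, int, int, int]] = []
        # hypothesis TOP: fwd read left on the C->T form, rc(rev) right
        left_t = transform_ct(a1)
        right_t = transform_ct(revcomp_array(a2))
        for contig, ls, lmm in _align_component(index, left_t, "CT", max_mismatches):
            for contig2, rs, rmm in _align_component(index, right_t, "CT", max_mismatches):
                if contig2 != contig or rs < ls:
                    continue
                if rs + len(a2) - ls > max_insert:
                    continue
                placements.append((lmm + rmm, TOP, contig, ls, rs, lmm, rmm))
        # hypothesis BOTTOM: rev read left on the G->A form, rc(fwd) right
        left_b = transform_ga(a2)
        right_b = transform_ga(revcomp_array(a1))
        for contig, ls, lmm in _align_component(index, left_b, "GA", max_mismatches):
            for contig2, rs, rmm in _align_component(index, right_b, "GA", max_mismatches):
                if contig2 != contig or rs < ls:
                    continue
                if rs + len(a1) - ls > max_insert:
                    continue
                placements.append((lmm + rmm, BOTTOM, contig, ls, rs, lmm, rmm))
        if not placements:
            continue
        best = min(p[0] for p in placements)
        best_placements = [p for p in placements if p[0] == best]
        if len(best_placements) != 1:
            continue  # not uniquely aligned
        score, strand, contig, ls, rs, lmm, rmm = best_placements[0]
        if strand == TOP:
            fwd = AlignedRead(r1.name, contig, ls, ls + len(a1), TOP, "fwd", lmm, a1)
            rev = AlignedRead(r1.name, contig, rs, rs + len(a2), TOP, "rev", rmm, revcomp_array(a2))
        else:
            fwd = AlignedRead(r1.name, contig, rs, rs + len(a1), BOTTOM, "fwd", rmm, revcomp_array(a1))
            rev = AlignedRead(r1.name, contig, ls, ls + len(a2), BOTTOM, "rev", lmm, a2)
        out.append(AlignedPair(fwd, rev, strand, contig, score))
    return out


def build_cut_boundary_index(
    cut_sites: Mapping[str, Sequence[CutSite]], enzymes: Mapping[str, Enzyme]
) -> dict[str, tuple[dict[int, str], dict[int, str]]]:
    """Per contig: {left boundary -> enzyme}, {right filled boundary -> enzyme}.

    A fragment's genome-left boundary equals the cut coordinate; its
    genome-right boundary after end repair equals cut + overhang.
    """
    out = {}
    for contig, sites in cut_sites.items():
        left = {}
        right = {}
        for s in sites:
            left.setdefault(s.position, s.enzyme)
            right.setdefault(s.position + enzymes[s.enzyme].overhang_len, s.enzyme)
        out[contig] = (left, right)
    return out


def enzyme_end_filter_and_mask(
    pairs: Sequence[AlignedPair],
    cut_sites: Mapping[str, Sequence[CutSite]],
    enzymes: Mapping[str, Enzyme],
    apply_mask: bool = True,
) -> tuple[list[AlignedPair], dict]:
    """Retain pairs with a digestion-site boundary at an outer end; mask fill-in.

    A pair passes when its genome-left coordinate is a cut site or its
    genome-right coordinate is a cut site plus that enzyme's overhang
    (tolerance 0 bp).  For retained pairs the reverse read's 5'-end bases
    that were filled in during end repair (the boundary enzyme's overhang:
    2 for MspI, 3 for ApeKI) are masked out of all counting.
    """
    bounds = build_cut_boundary_index(cut_sites, enzymes)
    kept = []
    for pair in pairs:
        left_map, right_map = bounds.get(pair.contig, ({}, {}))
        left_hit = pair.left in left_map
        right_hit = pair.right in right_map
        if not (left_hit or right_hit):
            continue
        mask = 0
        if pair.strand == TOP and right_hit:
            mask = enzymes[right_map[pair.right]].overhang_len
        elif pair.strand == BOTTOM and left_hit:
            mask = enzymes[left_map[pair.left]].overhang_len
        pair.r_rev.mask_len = mask if apply_mask else 0
        kept.append(pair)
    return kept, {
        "pairs_in": len(pairs),
        "pairs_kept": len(kept),
        "pairs_dropped": len(pairs) - len(kept),
    }


def _vote_arrays(genome: Mapping[str, str]):
    refs = {c: seq_to_array(s) for c, s in genome.items()}
    is_cpg_c = {}
    is_cpg_g = {}
    for contig, arr in refs.items():
        c = np.zeros(len(arr), dtype=bool)
        g = np.zeros(len(arr), dtype=bool)
        if len(arr) > 1:
            cpg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
            c[:-1] = cpg
            g[1:] = cpg
        is_cpg_c[contig] = c
        is_cpg_g[contig] = g
    return refs, is_cpg_c, is_cpg_g


def call_cpg_methylation(
    pairs: Sequence[AlignedPair], genome: Mapping[str, str]
) -> list[CpGCall]:
    """Per-CpG methylated/unmethylated counts from filtered, masked pairs."""
    _, is_cpg_c, is_cpg_g = _vote_arrays(genome)
    meth = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.items()}
    unmeth = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.items()}
    for pair in pairs:
        for read in pair.reads:
            pos = np.arange(read.start, read.end)
            bases = read.bases
            mlo, mhi = read.masked_interval()
            keep = (pos < mlo) | (pos >= mhi)
            pos, bases = pos[keep], bases[keep]
            if read.strand == TOP:
                sel = is_cpg_c[read.contig][pos]
                p, b = pos[sel], bases[sel]
                np.add.at(meth[read.contig], p[b == ord("C")], 1)
                np.add.at(unmeth[read.contig], p[b == ord("T")], 1)
            else:
                sel = is_cpg_g[read.contig][pos]
                p, b = pos[sel], bases[sel]
                np.add.at(meth[read.contig], p[b == ord("G")] - 1, 1)
                np.add.at(unmeth[read.contig], p[b == ord("A")] - 1, 1)
    calls = []
    for contig in genome:
        covered = np.where((meth[contig] + unmeth[contig]) > 0)[0]
        for p in covered:
            calls.append(CpGCall(contig, int(p), int(meth[contig][p]), int(unmeth[contig][p])))
    return calls


def estimate_conversion_rate(
    pairs: Sequence[AlignedPair],
    genome: Mapping[str, str],
    lambda_contig: str = "lambda_spike",
) -> float:
    """Conversion rate = T / (C + T) over all cytosines of the spike contig.

    Counts both strands and all contexts (the spike is fully unmethylated,
    so every retained C should read as T at the true conversion rate).
    Returns NaN with a warning when the spike has no coverage.
    """
    if lambda_contig not in genome:
        raise KeyError(f"spike contig {lambda_contig!r} absent from reference")
    ref = seq_to_array(genome[lambda_contig])
    is_c = ref == ord("C")
    is_g = ref == ord("G")
    converted = unconverted = 0
    for pair in pairs:
        if pair.contig != lambda_contig:
            continue
        for read in pair.reads:
            pos = np.arange(read.start, read.end)
            bases = read.bases
            mlo, mhi = read.masked_interval()
            keep = (pos < mlo) | (pos >= mhi)
            pos, bases = pos[keep], bases[keep]
            if read.strand == TOP:
                sel = is_c[pos]
                b = bases[sel]
                unconverted += int((b == ord("C")).sum())
                converted += int((b == ord("T")).sum())
            else:
                sel = is_g[pos]
                b = bases[sel]
                unconverted += int((b == ord("G")).sum())
                converted += int((b == ord("A")).sum())
    total = converted + unconverted
    if total == 0:
        warnings.warn("no aligned coverage on the spike contig; conversion rate undefined")
        return math.nan
    return converted / total


def load_sam_pairs(path: str, genome: Mapping[str, str]) -> list[AlignedPair]:
    """External-aligner plug-in: import ungapped paired alignments from SAM/BAM.

    Strand of origin is taken from the Bismark-style ``XG`` tag (``CT`` =
    top-converted, ``GA`` = bottom-converted) when present, otherwise
    inferred from the orientation of read 1 (forward = top).
    """
    import pysam

    by_name: dict[str, dict[str, "pysam.AlignedSegment"]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            slot = "r1" if rec.is_read1 else "r2"
            by_name.setdefault(rec.query_name, {})[slot] = rec
    out = []
    for name, mates in sorted(by_name.items()):
        if "r1" not in mates or "r2" not in mates:
            continue
        rec1, rec2 = mates["r1"], mates["r2"]
        if rec1.reference_name != rec2.reference_name:
            continue
        if rec1.has_tag("XG"):
            strand = TOP if rec1.get_tag("XG") == "CT" else BOTTOM
        else:
            strand = TOP if not rec1.is_reverse else BOTTOM
        reads = {}
        for mate, rec in (("fwd", rec1), ("rev", rec2)):
            bases = seq_to_array(rec.query_sequence)
            reads[mate] = AlignedRead(
                name,
                rec.reference_name,
                rec.reference_start,
                rec.reference_start + len(bases),
                strand,
                mate,
                int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                bases,
            )
        score = reads["fwd"].mismatches + reads["rev"].mismatches
        out.append(AlignedPair(reads["fwd"], reads["rev"], strand, rec1.reference_name, score))
    return out
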