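"""Genomic element definitions: CpG islands, shores, promoters, gene parts.

CpG islands follow the classic composition criteria: length strictly greater
than 200 bp, GC fraction strictly greater than 0.5 and observed/expected CpG
ratio strictly greater than 0.6, where

    O/E = (#CG dinucleotides * region length) / (#C * #G).

Detection slides a 200 bp window (step 1), merges overlapping qualifying
windows and re-validates each merged region on its final extent (greedy
trimming from the ends if the merged extent fails).

Promoters span 2200 bp upstream to 500 bp downstream of the TSS; shores are
the 2 kb flanks of each island with island bases subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

ELEMENT_CLASSES = (
    "CGI",
    "SHORE",
    "PROMOTER",
    "INTRON",
    "CDS",
    "UTR5",
    "UTR3",
    "DOWNSTREAM",
    "ENHANCER",
    "OTHER",
)

PROMOTER_UPSTREAM = 2200
PROMOTER_DOWNSTREAM = 500
SHORE_LENGTH = 2000

CGI_MIN_LENGTH = 200  # strict: region length must exceed this
CGI_MIN_GC = 0.5
CGI_MIN_OE = 0.6


@dataclass(frozen=True)
class GenomicInterval:
    contig: str
    start: int
    end: int
    strand: str = "."
    element_class: str = "OTHER"
    id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.contig}:{self.start}-{self.end}")
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    tss: int  # 0-based position of the first transcribed base
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons must be sorted, non-overlapping")
            prev_end = e


def _composition(seq_codes: np.ndarray) -> tuple[float, float]:
    """(GC fraction, O/E CpG ratio) of an encoded A/C/G/T/N sequence."""
    n = len(seq_codes)
    is_c = seq_codes == _C
    is_g = seq_codes == _G
    c = int(is_c.sum())
    g = int(is_g.sum())
    cg = int((is_c[:-1] & is_g[1:]).sum()) if n > 1 else 0
    gc = (c + g) / n if n else 0.0
    oe = (cg * n) / (c * g) if c and g else 0.0
    return gc, oe


_A, _C, _G, _T, _N = 0, 1, 2, 3, 4
_CODE = np.full(256, _N, dtype=np.int8)
for _b, _v in zip(b"ACGT", (_A, _C, _G, _T)):
    _CODE[_b] = _v
    _CODE[_b + 32] = _v  # lowercase


def encode_sequence(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _region_valid(codes: np.ndarray) -> bool:
    gc, oe = _composition(codes)
    return len(codes) > CGI_MIN_LENGTH and gc > CGI_MIN_GC and oe > CGI_MIN_OE


def _trim_to_valid(codes: np.ndarray, start: int, end: int) -> tuple[int, int] | None:
    """Greedily trim [start, end) from either end until it validates."""
    while end - start > CGI_MIN_LENGTH:
        region = codes[start:end]
        if _region_valid(region):
            return start, end
        # trim the end whose removal leaves the better-composed region
        def score(s, e):
            gc, oe = _composition(codes[s:e])
            return min((gc - CGI_MIN_GC) / CGI_MIN_GC, (oe - CGI_MIN_OE) / CGI_MIN_OE)

        if score(start + 1, end) >= score(start, end - 1):
            start += 1
        else:
            end -= 1
    return None


def detect_cgis(genome: Mapping[str, str], window: int = 200) -> list[GenomicInterval]:
    """De novo CpG island detection by sliding-window merge-and-revalidate."""
    islands: list[GenomicInterval] = []
    for contig, seq in genome.items():
        n = len(seq)
        if n < window:
            log.info("contig %s shorter than %d bp window; skipped", contig, window)
            continue
        codes = encode_sequence(seq)
        is_c = (codes == _C).astype(np.int64)
        is_g = (codes == _G).astype(np.int64)
        is_cg = np.zeros(n, dtype=np.int64)
        if n > 1:
            is_cg[:-1] = (codes[:-1] == _C) & (codes[1:] == _G)
        cum_c = np.concatenate([[0], np.cumsum(is_c)])
        cum_g = np.concatenate([[0], np.cumsum(is_g)])
        cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
        starts = np.arange(0, n - window + 1)
        c = cum_c[starts + window] - cum_c[starts]
        g = cum_g[starts + window] - cum_g[starts]
        # CG dinucleotides fully inside the window
        cg = cum_cg[starts + window - 1] - cum_cg[starts]
        gc_ok = (c + g) / window > CGI_MIN_GC
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(c * g > 0, cg * window / np.maximum(c * g, 1), 0.0)
        qual = gc_ok & (oe > CGI_MIN_OE)
        qpos = starts[qual]
        if qpos.size == 0:
            continue
        # merge overlapping qualifying windows (gap between starts < window)
        breaks = np.where(np.diff(qpos) >= window)[0]
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [qpos.size - 1]])
        idx = 0
        for rs, re_ in zip(run_starts, run_ends):
            lo, hi = int(qpos[rs]), int(qpos[re_]) + window
            trimmed = _trim_to_valid(codes, lo, hi)
            if trimmed is None:
                continue
            lo, hi = trimmed
            islands.append(
                GenomicInterval(contig, lo, hi, ".", "CGI", f"CGI_{contig}_{idx}")
            )
            idx += 1
    return islands


def derive_promoters(
    genes: Iterable[GeneModel], contig_lengths: Mapping[str, int] | None = None
) -> list[GenomicInterval]:
    """Promoter = 2200 bp upstream to 500 bp downstream of the TSS.

    For a + strand TSS t this is [t-2200, t+500); for a - strand TSS the same
    distances reflected: [t-499, t+2201). Clamped to the contig.
    """
    out = []
    for gene in genes:
        t = gene.tss
        if gene.strand == "+":
            start, end = t - PROMOTER_UPSTREAM, t + PROMOTER_DOWNSTREAM
        else:
            start, end = t - (PROMOTER_DOWNSTREAM - 1), t + PROMOTER_UPSTREAM + 1
        start = max(0, start)
        if contig_lengths is not None:
            end = min(end, contig_lengths[gene.contig])
        if start < end:
            out.append(
                GenomicInterval(gene.contig, start, end, gene.strand, "PROMOTER", gene.gene_id)
            )
    return out


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _subtract(interval: tuple[int, int], blockers: list[tuple[int, int]]) -> list[tuple[int, int]]:
    s, e = interval
    pieces = []
    for bs, be in blockers:
        if be <= s or bs >= e:
            continue
        if bs > s:
            pieces.append((s, bs))
        s = max(s, be)
        if s >= e:
            break
    if s < e:
        pieces.append((s, e))
    return pieces


def derive_shores(
    cgis: Sequence[GenomicInterval], contig_lengths: Mapping[str, int] | None = None
) -> list[GenomicInterval]:
    """2 kb flanks of each island, CGI bases subtracted, abutting pieces merged."""
    by_contig: dict[str, list[GenomicInterval]] = {}
    for cgi in cgis:
        by_contig.setdefault(cgi.contig, []).append(cgi)
    shores = []
    for contig, islands in by_contig.items():
        blockers = _merge_intervals([(c.start, c.end) for c in islands])
        clen = contig_lengths[contig] if contig_lengths else None
        pieces: list[tuple[int, int]] = []
        for c in islands:
            for lo, hi in ((c.start - SHORE_LENGTH, c.start), (c.end, c.end + SHORE_LENGTH)):
                lo = max(0, lo)
                if clen is not None:
                    hi = min(hi, clen)
                if lo < hi:
                    pieces.extend(_subtract((lo, hi), blockers))
        for i, (s, e) in enumerate(_merge_intervals(pieces)):
            shores.append(GenomicInterval(contig, s, e, ".", "SHORE", f"SHORE_{contig}_{i}"))
    return shores


def gene_part_elements(
    genes: Iterable[GeneModel], downstream: int = 2000,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Introns (gaps between exons) and downstream regions from gene models."""
    out = []
    for gene in genes:
        for i, ((_, e1), (s2, _)) in enumerate(zip(gene.exons[:-1], gene.exons[1:])):
            if e1 < s2:
                out.append(
                    GenomicInterval(
                        gene.contig, e1, s2, gene.strand, "INTRON", f"{gene.gene_id}_intron{i}"
                    )
                )
        if gene.exons:
            if gene.strand == "+":
                lo, hi = gene.exons[-1][1], gene.exons[-1][1] + downstream
            else:
                lo, hi = gene.exons[0][0] - downstream, gene.exons[0][0]
            lo = max(0, lo)
            if contig_lengths is not None:
                hi = min(hi, contig_lengths[gene.contig])
            if lo < hi:
                out.append(
                    GenomicInterval(gene.contig, lo, hi, gene.strand, "DOWNSTREAM",
                                    f"{gene.gene_id}_down")
                )
    return out


def build_element_index(elements: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for el in elements:
        trees.setdefault(el.contig, IntervalTree()).addi(el.start, el.end, el)
    return trees


def overlap_elements(
    positions: Iterable[tuple[str, int]], elements: Sequence[GenomicInterval]
) -> dict[tuple[str, int], set[str]]:
    """Multi-label element-class assignment for point positions.

    Every class whose interval contains the position is reported (no
    precedence); positions inside no element map to {"OTHER"}.
    """
    trees = build_element_index(elements)
    out: dict[tuple[str, int], set[str]] = {}
    for contig, pos in positions:
        tree = trees.get(contig)
        classes = {iv.data.element_class for iv in tree[pos]} if tree is not None else set()
        out[(contig, pos)] = classes or {"OTHER"}
    return out


def elements_to_bed(elements: Sequence[GenomicInterval]) -> str:
    lines = [
        f"{e.contig}\t{e.start}\t{e.end}\t{e.element_class}:{e.id}\t0\t{e.strand}"
        for e in elements
    ]
    return "\n".join(lines) + ("\n" if lines else "")
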