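"""Design-mode CpG coverage prediction for a digest + size selection + layout.

Given size-selected fragments, predicts which CpG dinucleotides the read
footprints interrogate and aggregates two metrics per element class:

* percentage of the class's CpG dinucleotides covered at depth >= 1/5/10;
* per element instance, the summed depth over its CpGs ("individual CpG
  measurements"), binned with a configurable top bin of > 25.

A CpG is interrogated when at least one base of the dinucleotide lies inside
an unmasked footprint; predicted depth counts fragments (times a read
multiplicity, default 1) covering it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .elements import GenomicInterval, encode_sequence, _C, _G
from .enzymes import Fragment

DEFAULT_DEPTH_THRESHOLDS = (1, 5, 10)
DEFAULT_BIN_EDGES = (0, 5, 15, 25)  # ">25" is the open top bin


@dataclass(frozen=True)
class ReadLayout:
    mode: str  # "SE" or "PE"
    read_length: int

    def __post_init__(self):
        if self.mode not in ("SE", "PE"):
            raise ValueError(f"unknown layout mode {self.mode!r}")
        if self.read_length <= 0:
            raise ValueError("read length must be positive")


PE50 = ReadLayout("PE", 50)
PE90 = ReadLayout("PE", 90)


@dataclass
class CpgDepthMap:
    """Predicted per-CpG depth. ``depth[contig]`` is indexed by the + strand
    C position of each CpG; zero entries mean uncovered."""

    cpg_positions: dict[str, np.ndarray]  # sorted + strand C positions per contig
    depth: dict[str, np.ndarray]  # same shape as cpg_positions

    def total_cpgs(self) -> int:
        return sum(len(p) for p in self.cpg_positions.values())

    def covered_count(self, threshold: int = 1) -> int:
        return sum(int((d >= threshold).sum()) for d in self.depth.values())

    def covered_positions(self, threshold: int = 1) -> set[tuple[str, int]]:
        return {
            (contig, int(p))
            for contig, pos in self.cpg_positions.items()
            for p in pos[self.depth[contig] >= threshold]
        }

    def as_dict(self) -> dict[tuple[str, int], int]:
        return {
            (contig, int(p)): int(d)
            for contig, pos in self.cpg_positions.items()
            for p, d in zip(pos, self.depth[contig])
            if d > 0
        }


@dataclass
class CoverageReport:
    class_table: pd.DataFrame  # per element_class x depth threshold
    element_bins: pd.DataFrame  # per element_class x measurement bin
    depth_thresholds: tuple[int, ...]
    bin_edges: tuple[int, ...]


def read_footprints(fragment: Fragment, layout: ReadLayout) -> list[tuple[int, int]]:
    """Covered intervals in filled-fragment coordinates, merged."""
    f_len = fragment.filled_length
    if f_len < 1:
        raise ValueError("fragment has no filled length")
    length = layout.read_length
    first = (0, min(length, f_len))
    if layout.mode == "SE":
        return [first]
    second = (max(0, f_len - length), f_len)
    if second[0] <= first[1]:  # reads overlap or abut: whole fragment
        return [(0, f_len)]
    return [first, second]


def cpg_positions(genome: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Positions of the + strand C of every CpG dinucleotide, per contig."""
    out = {}
    for contig, seq in genome.items():
        codes = encode_sequence(seq)
        if len(codes) > 1:
            out[contig] = np.where((codes[:-1] == _C) & (codes[1:] == _G))[0]
        else:
            out[contig] = np.array([], dtype=np.int64)
    return out


def predict_covered_cpgs(
    fragments_selected: Sequence[Fragment],
    layout: ReadLayout,
    genome: Mapping[str, str],
    mask_fill_in: bool = False,
    multiplicity: int = 1,
    enzymes: Mapping[str, "object"] | None = None,
) -> CpgDepthMap:
    """Predict interrogated CpGs and their depth under a read layout.

    A footprint interval [a, b) in genome coordinates interrogates the CpG at
    p iff a <= p+1 and p < b, i.e. p in [a-1, b); depth accumulates one count
    per fragment footprint (times ``multiplicity``).  With ``mask_fill_in``
    the right-end overhang (fill-in) bases of each filled fragment are
    excluded from its footprints.
    """
    # per-contig difference arrays over "CpG start coordinate" space
    diff: dict[str, np.ndarray] = {
        contig: np.zeros(len(seq) + 2, dtype=np.int64) for contig, seq in genome.items()
    }
    for frag in fragments_selected:
        if frag.contig not in diff:
            raise KeyError(f"fragment contig {frag.contig!r} absent from genome")
        fp = read_footprints(frag, layout)
        if mask_fill_in:
            fill_start = frag.end - frag.filled_start  # fragment-local fill start
            fp = [(a, min(b, fill_start)) for a, b in fp]
            fp = [(a, b) for a, b in fp if a < b]
        d = diff[frag.contig]
        # map to "CpG start coordinate" space ([a-1, b)) and merge per
        # fragment so each fragment counts once per CpG
        spans = sorted((max(0, frag.filled_start + a - 1), frag.filled_start + b) for a, b in fp)
        merged: list[list[int]] = []
        for a, b in spans:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            d[a] += multiplicity
            d[b] -= multiplicity
    cpgs = cpg_positions(genome)
    depth = {}
    for contig, d in diff.items():
        cum = np.cumsum(d[:-1])
        pos = cpgs[contig]
        depth[contig] = cum[pos] if len(pos) else np.array([], dtype=np.int64)
    return CpgDepthMap(cpg_positions=cpgs, depth=depth)


def _bin_label(total: int, edges: Sequence[int]) -> str:
    # edges like (0, 5, 15, 25) -> "0", "1-5", "6-15", "16-25", ">25"
    if total <= edges[0]:
        return str(edges[0]) if edges[0] == 0 else f"<={edges[0]}"
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo < total <= hi:
            return f"{lo + 1}-{hi}"
    return f">{edges[-1]}"


def bin_labels(edges: Sequence[int]) -> list[str]:
    labels = [str(edges[0]) if edges[0] == 0 else f"<={edges[0]}"]
    labels += [f"{lo + 1}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">{edges[-1]}")
    return labels


def coverage_report(
    covered: CpgDepthMap,
    elements: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    depth_thresholds: Sequence[int] = DEFAULT_DEPTH_THRESHOLDS,
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> CoverageReport:
    """Aggregate per-element-class coverage and per-element measurement bins.

    Element assignment is multi-label: a CpG inside both a promoter and a CGI
    counts toward both classes, so class percentages do not sum to 100.
    """
    for el in elements:
        if el.contig not in covered.cpg_positions:
            raise KeyError(f"element contig {el.contig!r} absent from genome")
    thresholds = tuple(depth_thresholds)
    edges = tuple(bin_edges)
    classes = sorted({el.element_class for el in elements} | {"OTHER"})

    # per-contig class membership masks over CpG indices
    class_rows = []
    by_class: dict[str, dict[str, np.ndarray]] = {
        cls: {
            contig: np.zeros(len(pos), dtype=bool)
            for contig, pos in covered.cpg_positions.items()
        }
        for cls in classes
    }
    for el in elements:
        pos = covered.cpg_positions[el.contig]
        lo, hi = np.searchsorted(pos, [el.start, el.end])
        by_class[el.element_class][el.contig][lo:hi] = True
    # OTHER: CpGs in no element
    for contig, pos in covered.cpg_positions.items():
        any_mask = np.zeros(len(pos), dtype=bool)
        for cls in classes:
            if cls != "OTHER":
                any_mask |= by_class[cls][contig]
        by_class["OTHER"][contig] |= ~any_mask

    for cls in classes:
        total = sum(int(m.sum()) for m in by_class[cls].values())
        for thr in thresholds:
            cov = sum(
                int((covered.depth[contig][m] >= thr).sum())
                for contig, m in by_class[cls].items()
            )
            pct = 100.0 * cov / total if total else 0.0
            class_rows.append(
                {
                    "element_class": cls,
                    "depth_threshold": thr,
                    "total_cpgs": total,
                    "covered_cpgs": cov,
                    "pct_covered": pct,
                }
            )
    class_table = pd.DataFrame(class_rows)

    labels = bin_labels(edges)
    bin_counts: dict[str, dict[str, int]] = {
        cls: {lab: 0 for lab in labels} for cls in classes if cls != "OTHER"
    }
    for el in elements:
        pos = covered.cpg_positions[el.contig]
        lo, hi = np.searchsorted(pos, [el.start, el.end])
        total = int(covered.depth[el.contig][lo:hi].sum())
        bin_counts[el.element_class][_bin_label(total, edges)] += 1
    element_bins = (
        pd.DataFrame(bin_counts).T.rename_axis("element_class").reset_index()
        if bin_counts
        else pd.DataFrame()
    )
    return CoverageReport(class_table, element_bins, thresholds, edges)


def reads_per_informative_cpg(
    total_aligned_read_pairs: int, covered: CpgDepthMap, depth_threshold: int = 1
) -> float:
    """Aligned read pairs per CpG with depth >= threshold (NaN when none)."""
    if total_aligned_read_pairs < 0 or depth_threshold < 0:
        raise ValueError("negative inputs")
    informative = covered.covered_count(depth_threshold)
    if informative == 0:
        return math.nan
    return total_aligned_read_pairs / informative
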