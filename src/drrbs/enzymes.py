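"""Restriction enzymes, cut-site scanning and in silico digestion.

Enzymes are modelled by their IUPAC recognition motif and the position of the
top-strand cut within it (caret notation, e.g. MspI = ``C^CGG``).  For a
5'-overhang cutter the overhang length equals ``len(site) - 2 * cut_offset``;
those overhang bases are filled in during end repair and must be masked in
downstream methylation calling.  Blunt cutters have overhang 0.

Digestion is modelled as complete: every site on either strand is cut, and a
combined digest is the union of the single-enzyme cut sets (order of enzyme
addition is irrelevant).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

CONTIG_END = "CONTIG_END"

# genome alphabet accepted by the scanner; N in the genome never matches
# any motif code, including N in the motif (conservative).
_GENOME_ALPHABET = set("ACGTN")


_IUPAC_CODES = set("ACGTRYWSKMBDHVN")


def _iupac_class(code: str) -> str:
    """Regex character class for one IUPAC code (excludes genomic N)."""
    if code not in _IUPAC_CODES:
        raise ValueError(f"invalid IUPAC character {code!r} in recognition site")
    bases = ambiguous_dna_values[code].replace("U", "")
    return bases if len(bases) == 1 else f"[{bases}]"


def _motif_pattern(motif: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(_iupac_class(c) for c in motif) + ")")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with cut geometry.

    ``cut_offset`` is the number of bases 5' of the top-strand cut within the
    recognition site; ``overhang_len`` is the 5'-overhang length (the number
    of fill-in bases to mask downstream).
    """

    name: str
    recognition: str
    cut_offset: int
    overhang_len: int

    def __post_init__(self):
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition site")
        for c in self.recognition:
            _iupac_class(c)  # validates
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError(f"{self.name}: cut offset outside recognition site")
        if self.overhang_len < 0:
            raise ValueError(f"{self.name}: negative overhang")
        if self.is_palindromic and self.overhang_len != len(self.recognition) - 2 * self.cut_offset:
            raise ValueError(
                f"{self.name}: palindromic site implies overhang "
                f"{len(self.recognition) - 2 * self.cut_offset}, got {self.overhang_len}"
            )

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition

    @classmethod
    def from_caret(cls, name: str, site: str, overhang: int | None = None) -> "Enzyme":
        """Build from caret notation, e.g. ``C^CGG``.

        ``overhang`` overrides the derived 5'-overhang length; used to model
        blunt-represented cutters whose natural geometry is not a 5' overhang.
        """
        if site.count("^") != 1:
            raise ValueError(f"{name}: site {site!r} must contain exactly one '^'")
        offset = site.index("^")
        recognition = site.replace("^", "")
        derived = len(recognition) - 2 * offset
        if overhang is None:
            if derived < 0:
                raise ValueError(
                    f"{name}: cut {site!r} implies a negative (3') overhang; "
                    "supply an explicit overhang column"
                )
            overhang = derived
        return cls(name=name, recognition=recognition, cut_offset=offset, overhang_len=overhang)


@dataclass(frozen=True)
class CutSite:
    contig: str
    position: int  # 0-based between-base coordinate of the top-strand cut
    enzyme: str


@dataclass(frozen=True)
class Fragment:
    """Digestion product: partition interval plus end-repaired (filled) extent.

    ``start``/``end`` partition the contig between adjacent cuts;
    ``filled_start``/``filled_end`` describe the double-stranded fragment
    after fill-in (right end extended by the right enzyme's overhang).
    """

    contig: str
    start: int
    end: int
    left_enzyme: str = CONTIG_END
    right_enzyme: str = CONTIG_END
    filled_start: int = -1
    filled_end: int = -1

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def filled_length(self) -> int:
        return self.filled_end - self.filled_start


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length selection window (base pairs)."""

    min_len: int
    max_len: int

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(f"invalid size window [{self.min_len}, {self.max_len}]")

    def contains(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


def find_cut_sites(sequence: str, enzyme: Enzyme, contig: str = "") -> list[CutSite]:
    """All top-strand cut positions of ``enzyme`` in ``sequence``.

    Both strands are scanned; for a non-palindromic motif the reverse
    complement motif is scanned separately and its cut mapped to the top
    strand (for the 5'-overhang geometry modelled here the top-strand cut of
    a bottom-strand site at s is s + cut_offset, mirroring the forward case).
    Overlapping occurrences are all reported; the result is sorted and
    deduplicated.
    """
    seq = sequence.upper()
    bad = set(seq) - _GENOME_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    motifs = {enzyme.recognition}
    motifs.add(reverse_complement(enzyme.recognition))
    positions: set[int] = set()
    for motif in motifs:
        pat = _motif_pattern(motif)
        for m in pat.finditer(seq):
            positions.add(m.start() + enzyme.cut_offset)
    return [CutSite(contig, p, enzyme.name) for p in sorted(positions)]


def merged_cut_sites(
    genome: Mapping[str, str], enzymes: Iterable[Enzyme]
) -> dict[str, list[CutSite]]:
    """Per-contig sorted, deduplicated cut sites from all enzymes.

    When two enzymes cut at the same coordinate the label of the
    alphabetically first enzyme name is kept (deterministic).
    """
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    out: dict[str, list[CutSite]] = {}
    for contig, seq in genome.items():
        by_pos: dict[int, CutSite] = {}
        for enz in sorted(enzymes, key=lambda e: e.name):
            for site in find_cut_sites(seq, enz, contig):
                by_pos.setdefault(site.position, site)
        out[contig] = [by_pos[p] for p in sorted(by_pos)]
    return out


def digest_genome(genome: Mapping[str, str], enzymes: Iterable[Enzyme]) -> list[Fragment]:
    """Complete combined digestion of ``genome`` by ``enzymes``.

    Fragments partition each contig exactly; the filled interval extends the
    right end by the right enzyme's overhang (clamped to the contig).
    """
    if not genome:
        raise ValueError("empty genome")
    enzymes = list(enzymes)
    by_name = {e.name: e for e in enzymes}
    sites = merged_cut_sites(genome, enzymes)
    fragments: list[Fragment] = []
    for contig, seq in genome.items():
        n = len(seq)
        if n == 0:
            continue
        cuts = [s for s in sites[contig] if 0 < s.position < n]
        bounds = [(0, CONTIG_END)] + [(s.position, s.enzyme) for s in cuts] + [(n, CONTIG_END)]
        for (start, left), (end, right) in zip(bounds[:-1], bounds[1:]):
            right_ov = by_name[right].overhang_len if right != CONTIG_END else 0
            fragments.append(
                Fragment(
                    contig=contig,
                    start=start,
                    end=end,
                    left_enzyme=left,
                    right_enzyme=right,
                    filled_start=start,
                    filled_end=min(end + right_ov, n),
                )
            )
    return fragments


def size_select(
    fragments: Sequence[Fragment], window: SizeWindow, length_basis: str = "partition"
) -> list[Fragment]:
    """Retain fragments whose length lies in ``window`` (inclusive both ends).

    ``length_basis`` chooses the partition (insert) length or the filled
    (end-repaired) length. Order is preserved; input is not modified.
    """
    if length_basis not in ("partition", "filled"):
        raise ValueError(f"unknown length basis {length_basis!r}")
    key = (lambda f: f.length) if length_basis == "partition" else (lambda f: f.filled_length)
    return [f for f in fragments if window.contains(key(f))]


def fragments_to_bed(fragments: Sequence[Fragment]) -> str:
    """BED6 export: name = leftEnzyme_rightEnzyme, score = length."""
    lines = []
    for f in fragments:
        lines.append(
            f"{f.contig}\t{f.start}\t{f.end}\t{f.left_enzyme}_{f.right_enzyme}\t{f.length}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")
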