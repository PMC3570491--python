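import numpy as np
import pytest

from drrbs.io import default_enzymes


@pytest.fixture(scope="session")
def panel():
    return default_enzymes()


@pytest.fixture(scope="session")
def mspi(panel):
    return panel["MspI"]


@pytest.fixture(scope="session")
def apeki(panel):
    return panel["ApeKI"]


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of the implementation's helpers)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "W": "W",
       "S": "S", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
       "N": "N"}


def revcomp_iupac(motif: str) -> str:
    return "".join(_RC[c] for c in reversed(motif))


def brute_cut_positions(seq: str, enzyme) -> list[int]:
    """Exhaustive substring scan over both strand motifs."""
    seq = seq.upper()
    positions = set()
    for motif in {enzyme.recognition, revcomp_iupac(enzyme.recognition)}:
        L = len(motif)
        for i in range(len(seq) - L + 1):
            if all(seq[i + j] in IUPAC_SETS[motif[j]] for j in range(L)):
                positions.add(i + enzyme.cut_offset)
    return sorted(positions)


def brute_fragments(seq: str, enzymes) -> list[tuple[int, int, str, str, int, int]]:
    """(start, end, left enzyme, right enzyme, filled start, filled end)."""
    labelled: dict[int, str] = {}
    overhang = {e.name: e.overhang_len for e in enzymes}
    for e in sorted(enzymes, key=lambda e: e.name):
        for p in brute_cut_positions(seq, e):
            if 0 < p < len(seq):
                labelled.setdefault(p, e.name)
    bounds = [(0, "CONTIG_END")] + [(p, labelled[p]) for p in sorted(labelled)]
    bounds.append((len(seq), "CONTIG_END"))
    out = []
    for (s, le), (e_, re_) in zip(bounds[:-1], bounds[1:]):
        ov = overhang.get(re_, 0)
        out.append((s, e_, le, re_, s, min(e_ + ov, len(seq))))
    return out
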