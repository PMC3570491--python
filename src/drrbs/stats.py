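"""Region-level differential methylation, methylome concordance, and digital
gene expression (DGE) testing.

Differential methylation uses a Pearson chi-square (df = 1, no continuity
correction by default) on the region's pooled 2x2 table of methylated /
unmethylated CpG read counts, with the dual calling rule: p < 0.01 AND
absolute methylation-level difference > 0.20.

DGE uses the Audic-Claverie exact test for tag counts between two libraries,

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

which is the negative binomial NB(x+1, N1/(N1+N2)) in y.  The two-sided
p-value doubles the smaller of the two point-inclusive tails evaluated in
each orientation, p = min(1, 2*min(P(K >= y | x; N1,N2),
P(K >= x | y; N2,N1))); the two tails sum to 1 + p(y|x), making the test
exactly symmetric under (x, N1) <-> (y, N2).  Genes are called differentially
expressed at Benjamini-Hochberg FDR < 0.01 with a two-fold TPM change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from .calling import CpGCall
from .elements import GenomicInterval


@dataclass
class RegionCounts:
    region: GenomicInterval
    methylated: int
    unmethylated: int
    n_cpgs: int

    @property
    def depth(self) -> int:
        return self.methylated + self.unmethylated

    @property
    def level(self) -> float:
        return self.methylated / self.depth if self.depth else math.nan

    @property
    def covered(self) -> bool:
        return self.depth > 0


@dataclass
class DmrResult:
    region: GenomicInterval
    statistic: float
    p_value: float
    delta: float  # level_A - level_B
    is_dmr: bool


@dataclass
class DgeResult:
    gene: str
    count_a: int
    count_b: int
    library_size_a: int
    library_size_b: int
    p_value: float
    q_value: float = math.nan
    is_de: bool = False

    @property
    def tpm_a(self) -> float:
        return self.count_a / self.library_size_a * 1e6

    @property
    def tpm_b(self) -> float:
        return self.count_b / self.library_size_b * 1e6

    def fold_change(self, pseudocount: float = 1.0) -> float:
        """Fold change on TPM with a pseudocount of one read per library."""
        a = (self.count_a + pseudocount) / self.library_size_a * 1e6
        b = (self.count_b + pseudocount) / self.library_size_b * 1e6
        return max(a, b) / min(a, b)


def region_counts(
    calls: Sequence[CpGCall], regions: Sequence[GenomicInterval]
) -> list[RegionCounts]:
    """Sum methylated/unmethylated votes over the CpGs inside each region."""
    by_contig: dict[str, list[CpGCall]] = {}
    for call in calls:
        by_contig.setdefault(call.contig, []).append(call)
    positions = {
        contig: np.array(sorted(c.position for c in cs))
        for contig, cs in by_contig.items()
    }
    lookup = {
        contig: {c.position: c for c in cs} for contig, cs in by_contig.items()
    }
    out = []
    for region in regions:
        m = u = n = 0
        pos = positions.get(region.contig)
        if pos is not None and len(pos):
            lo, hi = np.searchsorted(pos, [region.start, region.end])
            for p in pos[lo:hi]:
                call = lookup[region.contig][int(p)]
                m += call.methylated
                u += call.unmethylated
                n += 1
        out.append(RegionCounts(region=region, methylated=m, unmethylated=u, n_cpgs=n))
    return out


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p for [[a, b], [c, d]] (df = 1)."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    stat = n * diff**2 / (r1 * r2 * c1 * c2)
    return float(stat), float(sps.chi2.sf(stat, df=1))


def chi_square_dmr(
    counts_a: RegionCounts,
    counts_b: RegionCounts,
    p_threshold: float = 0.01,
    delta_threshold: float = 0.20,
    yates: bool = False,
) -> DmrResult:
    """Chi-square DMR test with the dual p / level-difference rule."""
    stat, p = chi_square_2x2(
        counts_a.methylated, counts_a.unmethylated,
        counts_b.methylated, counts_b.unmethylated,
        yates=yates,
    )
    if counts_a.depth and counts_b.depth:
        delta = counts_a.level - counts_b.level
    else:
        delta = math.nan
    is_dmr = bool(p < p_threshold and abs(delta) > delta_threshold) if not math.isnan(delta) else False
    return DmrResult(region=counts_a.region, statistic=stat, p_value=p, delta=delta, is_dmr=is_dmr)


def methylome_correlation(
    calls_a: Sequence[CpGCall], calls_b: Sequence[CpGCall], min_depth: int = 5
) -> tuple[float, int]:
    """Pearson r of per-CpG levels over sites with depth >= min_depth in both."""
    a = {(c.contig, c.position): c for c in calls_a if c.depth >= min_depth}
    b = {(c.contig, c.position): c for c in calls_b if c.depth >= min_depth}
    shared = sorted(a.keys() & b.keys())
    if len(shared) < 2:
        return math.nan, len(shared)
    xs = np.array([a[k].level for k in shared])
    ys = np.array([b[k].level for k in shared])
    if np.std(xs) == 0 or np.std(ys) == 0:
        return math.nan, len(shared)
    r, _ = sps.pearsonr(xs, ys)
    return float(r), len(shared)


def audic_claverie_logpmf(x: int, y: int, n1: float, n2: float) -> float:
    """log p(y|x): probability of y tags in library 2 given x in library 1."""
    if x < 0 or y < 0 or n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be >= 0 and library sizes > 0")
    log_ratio = math.log(n2) - math.log(n1)
    return (
        y * log_ratio
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(n2 / n1)
    )


def audic_claverie_pmf(x: int, y: int, n1: float, n2: float) -> float:
    return math.exp(audic_claverie_logpmf(x, y, n1, n2))


def _upper_tail(x: int, y: int, n1: float, n2: float) -> float:
    """P(K >= y | x; N1, N2) in log space (K ~ NB(x+1, N1/(N1+N2)))."""
    if y == 0:
        return 1.0
    # sum the complement (finite) tail and subtract
    logs = [audic_claverie_logpmf(x, k, n1, n2) for k in range(y)]
    return float(max(0.0, 1.0 - math.exp(logsumexp(logs))))


def audic_claverie_test(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p-value, exactly symmetric in the samples.

    Doubles the smaller of the two point-inclusive tails
    P(K >= y | x; N1, N2) and P(K >= x | y; N2, N1), capped at 1.
    """
    a = _upper_tail(x, y, n1, n2)
    b = _upper_tail(y, x, n2, n1)
    return min(1.0, 2.0 * min(a, b))


def call_de_genes(
    genes: Sequence[tuple[str, int, int]],
    library_size_a: int,
    library_size_b: int,
    fdr_threshold: float = 0.01,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> list[DgeResult]:
    """Audic-Claverie + Benjamini-Hochberg FDR + fold-change DE calling.

    ``genes`` is a sequence of (gene id, count in A, count in B).  A gene is
    differentially expressed when q < ``fdr_threshold`` and the TPM fold
    change (pseudocount-stabilised) is >= ``fold_threshold``.
    """
    from statsmodels.stats.multitest import multipletests

    if library_size_a <= 0 or library_size_b <= 0:
        raise ValueError("library sizes must be positive")
    results = [
        DgeResult(
            gene=g,
            count_a=int(a),
            count_b=int(b),
            library_size_a=library_size_a,
            library_size_b=library_size_b,
            p_value=audic_claverie_test(int(a), int(b), library_size_a, library_size_b),
        )
        for g, a, b in genes
    ]
    if results:
        _, qvals, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
            r.is_de = bool(
                q < fdr_threshold and r.fold_change(pseudocount) >= fold_threshold
            )
    return results
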