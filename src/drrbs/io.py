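"""File formats and run configuration.

Coordinate convention: 0-based half-open everywhere internally; BED is
emitted natively, GTF is converted on read (1-based inclusive -> internal).
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .calling import CpGCall, FastqRead
from .coverage import ReadLayout
from .elements import ELEMENT_CLASSES, GeneModel, GenomicInterval
from .enzymes import Enzyme, SizeWindow
from .simulate import ReadPair


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq_pairs(pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            f2.write(f"@{p.name}/2\n{p.r2_seq}\n+\n{p.r2_qual}\n")


def read_fastq_pairs(
    path1: str | Path, path2: str | Path
) -> list[tuple[FastqRead, FastqRead]]:
    out = []
    with _open_text(path1) as f1, _open_text(path2) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            name1 = t1.split()[0].removesuffix("/1")
            out.append((FastqRead(name1, s1, q1), FastqRead(name1, s2, q2)))
    return out


# -------------------------------------------------------------- enzyme table

def parse_enzyme_rows(rows: Iterable[tuple[int, str]]) -> list[Enzyme]:
    enzymes: list[Enzyme] = []
    seen = set()
    for lineno, line in rows:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"enzyme table line {lineno}: expected name<TAB>site")
        name, site = fields[0], fields[1]
        overhang = None
        if len(fields) >= 3 and fields[2]:
            overhang = int(fields[2])
            if overhang < 0:
                raise ValueError(f"enzyme table line {lineno}: negative overhang")
        if name in seen:
            raise ValueError(f"enzyme table line {lineno}: duplicate enzyme {name!r}")
        seen.add(name)
        try:
            enzymes.append(Enzyme.from_caret(name, site, overhang))
        except ValueError as exc:
            raise ValueError(f"enzyme table line {lineno}: {exc}") from exc
    return enzymes


def load_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Tab-separated enzyme definitions: name, site-with-caret[, overhang]."""
    with open(path) as fh:
        return parse_enzyme_rows(enumerate(fh, start=1))


def default_enzymes() -> dict[str, Enzyme]:
    """The shipped panel (MspI, ApeKI, TaqaI, BssSI, ...)."""
    text = resources.files("drrbs").joinpath("data/enzymes.tsv").read_text()
    return {e.name: e for e in parse_enzyme_rows(enumerate(text.splitlines(), start=1))}


# ---------------------------------------------------------------- BED / GTF

def read_bed_elements(path: str | Path, element_class: str = "OTHER") -> list[GenomicInterval]:
    """BED3/6; an element class embedded as CLASS:id in the name wins."""
    out = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            contig, start, end = f[0], int(f[1]), int(f[2])
            cls, eid = element_class, f"{element_class}_{i}"
            if len(f) > 3 and f[3]:
                name = f[3]
                if ":" in name and name.split(":", 1)[0] in ELEMENT_CLASSES:
                    cls, eid = name.split(":", 1)
                else:
                    eid = name
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(contig, start, end, strand, cls, eid))
    return out


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Gene models from GTF exon records; TSS = 5'-most exon boundary."""
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].rstrip(";").split(";")
                if " " in kv.strip()
            )
            gene_id = attrs.get("gene_id", "").strip('"')
            start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based inclusive
            exons.setdefault(gene_id, []).append((f[0], f[6], start, end))
    genes = []
    for gene_id, rows in sorted(exons.items()):
        contig, strand = rows[0][0], rows[0][1]
        ivs = sorted((s, e) for _, _, s, e in rows)
        tss = ivs[0][0] if strand == "+" else ivs[-1][1] - 1
        genes.append(GeneModel(gene_id, contig, strand, tss, tuple(ivs)))
    return genes


def read_bed12_genes(path: str | Path) -> list[GeneModel]:
    genes = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            contig, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
            genes.append(GeneModel(name, contig, strand, tss, exons))
    return genes


# ------------------------------------------------------------------- outputs

def stage_header(stage: str, param_hash: str) -> str:
    return f"# drrbs stage={stage} params={param_hash}\n"


def write_calls_tsv(
    calls: Sequence[CpGCall], path: str | Path, stage: str = "call", param_hash: str = "-"
) -> None:
    with open(path, "w") as fh:
        fh.write(stage_header(stage, param_hash))
        fh.write("contig\tposition\tstrand\tmethylated\tunmethylated\tlevel\n")
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.position}\t+\t{c.methylated}\t{c.unmethylated}\t{c.level:.6f}\n"
            )


def read_calls_tsv(path: str | Path) -> list[CpGCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("contig\t"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(CpGCall(f[0], int(f[1]), int(f[3]), int(f[4])))
    return out


def write_bedgraph(
    calls: Sequence[CpGCall], path: str | Path, stage: str = "call", param_hash: str = "-"
) -> None:
    with open(path, "w") as fh:
        fh.write(stage_header(stage, param_hash))
        for c in calls:
            fh.write(f"{c.contig}\t{c.position}\t{c.position + 2}\t{c.level:.6f}\n")


# --------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Declarative configuration for a reproducible pipeline run."""

    seed: int
    outdir: str
    stages: tuple[str, ...] = ("design", "simulate", "call", "dmr", "dge")
    enzymes: tuple[str, ...] = ("MspI", "ApeKI")
    enzyme_table: str | None = None
    genome_fasta: str | None = None
    genes_gtf: str | None = None
    size_window: tuple[int, int] = (40, 220)
    layout_mode: str = "PE"
    read_length: int = 50
    sim: dict = field(default_factory=dict)
    max_mismatches: int = 2
    depth_threshold: int = 5
    p_threshold: float = 0.01
    delta_threshold: float = 0.20
    fdr_threshold: float = 0.01
    fold_threshold: float = 2.0
    dmr_fraction: float = 0.3  # fraction of islands truly shifted in sample B
    dmr_beta: tuple[float, float] = (12.0, 8.0)

    VALID_STAGES = ("design", "simulate", "call", "dmr", "dge")

    def __post_init__(self):
        for s in self.stages:
            if s not in self.VALID_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if not (0 < self.p_threshold <= 1 and 0 <= self.delta_threshold <= 1):
            raise ValueError("thresholds out of range")
        if not (0 < self.fdr_threshold <= 1 and self.fold_threshold >= 1):
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "enzymes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        for key in ("size_window", "dmr_beta"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("enzyme_table", "genome_fasta", "genes_gtf"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def window(self) -> SizeWindow:
        return SizeWindow(*self.size_window)

    def layout(self) -> ReadLayout:
        return ReadLayout(self.layout_mode, self.read_length)

    def param_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
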