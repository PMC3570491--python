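"""Config-driven pipeline tying the stages into a reproducible run.

Stages (any subset, executed in canonical order):

* ``design``   — digest + size-select and predict CpG coverage for the
  single-enzyme (first enzyme) and full double-enzyme digests.
* ``simulate`` — synthesize genome/methylome and paired bisulfite reads
  (two samples when ``dmr`` is requested).
* ``call``     — QC, three-letter alignment, enzyme-end filter, fill-in
  masking, per-CpG calls and spike-in conversion-rate estimation.
* ``dmr``      — chi-square differential methylation over island and
  promoter regions between the two samples.
* ``dge``      — Audic-Claverie digital expression test on simulated tag
  counts.

All randomness derives from the single config seed; rerunning an identical
config produces byte-identical outputs, and a manifest records inputs,
parameters and per-stage read accounting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

from . import calling, coverage, elements, enzymes, io, simulate, stats

log = logging.getLogger(__name__)

STAGE_ORDER = ("design", "simulate", "call", "dmr", "dge")


def _write_table(df, path: Path, stage: str, param_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(io.stage_header(stage, param_hash))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def _derive_elements(genome, genes, cgis):
    contig_lengths = {c: len(s) for c, s in genome.items()}
    shores = elements.derive_shores(cgis, contig_lengths)
    promoters = elements.derive_promoters(genes, contig_lengths)
    parts = elements.gene_part_elements(genes, contig_lengths=contig_lengths)
    return list(cgis) + shores + promoters + parts


def run_pipeline(config: io.RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phash = config.param_hash()
    manifest: dict = {
        "tool": "drrbs",
        "seed": config.seed,
        "parameter_hash": phash,
        # outdir is implied by the manifest's own location; omitting it keeps
        # manifests byte-identical across reruns into different directories
        "config": {k: v for k, v in asdict(config).items() if k != "outdir"},
        "stages": [s for s in STAGE_ORDER if s in config.stages],
        "outputs": {},
        "metrics": {},
    }

    panel = (
        {e.name: e for e in io.load_enzyme_table(config.enzyme_table)}
        if config.enzyme_table
        else io.default_enzymes()
    )
    try:
        enz = {name: panel[name] for name in config.enzymes}
    except KeyError as exc:
        raise KeyError(f"enzyme {exc} not in the enzyme table") from exc
    window = config.window()
    layout = config.layout()
    sim_cfg = simulate.SimConfig(
        seed=config.seed, size_window=window, layout=layout, **config.sim
    )

    # --- genome ------------------------------------------------------------
    genes: list[elements.GeneModel]
    if config.genome_fasta:
        genome = io.read_fasta(config.genome_fasta)
        genes = io.read_gtf_genes(config.genes_gtf) if config.genes_gtf else []
        truth_cgis = None
    else:
        genome, truth_cgis, genes = simulate.synthesize_genome(sim_cfg)
    analysis_genome = {c: s for c, s in genome.items() if c != simulate.LAMBDA_CONTIG}
    cgis = elements.detect_cgis(analysis_genome)
    all_elements = _derive_elements(analysis_genome, genes, cgis)

    fragments = enzymes.digest_genome(genome, enz.values())
    selected = enzymes.size_select(fragments, window)
    cut_sites = enzymes.merged_cut_sites(genome, enz.values())
    manifest["metrics"]["fragments_total"] = len(fragments)
    manifest["metrics"]["fragments_selected"] = len(selected)

    if "design" in config.stages:
        single = [next(iter(enz.values()))]
        frag_single = enzymes.size_select(enzymes.digest_genome(genome, single), window)
        rows = []
        for label, frags in (("single", frag_single), ("double", selected)):
            genomic = [f for f in frags if f.contig != simulate.LAMBDA_CONTIG]
            covered = coverage.predict_covered_cpgs(genomic, layout, analysis_genome)
            report = coverage.coverage_report(covered, all_elements, analysis_genome)
            df = report.class_table.copy()
            df.insert(0, "digest", label)
            rows.append(df)
            _write_table(
                report.element_bins, outdir / f"design_bins_{label}.tsv", "design", phash
            )
        import pandas as pd

        _write_table(pd.concat(rows), outdir / "design_coverage.tsv", "design", phash)
        io.write_fasta(genome, outdir / "genome.fa")
        with open(outdir / "fragments.bed", "w") as fh:
            fh.write(enzymes.fragments_to_bed(selected))
        manifest["outputs"]["design"] = [
            "design_coverage.tsv",
            "design_bins_single.tsv",
            "design_bins_double.tsv",
            "genome.fa",
            "fragments.bed",
        ]

    samples = ["A", "B"] if "dmr" in config.stages else ["A"]
    truths: dict[str, simulate.MethylomeTruth] = {}
    shifted_regions: list[elements.GenomicInterval] = []
    if "simulate" in config.stages or "call" in config.stages or "dmr" in config.stages:
        truth_a = simulate.assign_methylome(genome, cgis, seed=config.seed)
        truths["A"] = truth_a
        if "B" in samples:
            import numpy as np

            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 606]))
            pick = rng.random(len(cgis)) < config.dmr_fraction
            shifted_regions = [c for c, p in zip(cgis, pick) if p]
            truths["B"] = simulate.perturb_methylome(
                truth_a, shifted_regions, config.dmr_beta, config.seed
            )

    if "simulate" in config.stages:
        io.write_fasta(genome, outdir / "genome.fa")
        with open(outdir / "truth_elements.bed", "w") as fh:
            fh.write(elements.elements_to_bed(truth_cgis or cgis))
        files = ["genome.fa", "truth_elements.bed"]
        for stream, sample in enumerate(samples):
            pairs = simulate.simulate_reads(
                genome, truths[sample], selected, sim_cfg, enz, stream=stream
            )
            io.write_fastq_pairs(
                pairs, outdir / f"reads_{sample}_1.fq", outdir / f"reads_{sample}_2.fq"
            )
            with open(outdir / f"truth_reads_{sample}.tsv", "w") as fh:
                fh.write(io.stage_header("simulate", phash))
                fh.write("name\tcontig\tfragment_start\tfragment_end\tfilled_end\tstrand\n")
                for p in pairs:
                    fh.write(
                        f"{p.name}\t{p.contig}\t{p.fragment_start}\t{p.fragment_end}"
                        f"\t{p.filled_end}\t{p.strand}\n"
                    )
            with open(outdir / f"truth_methylome_{sample}.tsv", "w") as fh:
                fh.write(io.stage_header("simulate", phash))
                fh.write("contig\tposition\tprobability\n")
                for contig in sorted(truths[sample].probs):
                    for pos in sorted(truths[sample].probs[contig]):
                        fh.write(f"{contig}\t{pos}\t{truths[sample].probs[contig][pos]:.6f}\n")
            files += [
                f"reads_{sample}_1.fq",
                f"reads_{sample}_2.fq",
                f"truth_reads_{sample}.tsv",
                f"truth_methylome_{sample}.tsv",
            ]
            manifest["metrics"][f"read_pairs_{sample}"] = len(pairs)
        manifest["outputs"]["simulate"] = files

    calls_by_sample: dict[str, list[calling.CpGCall]] = {}
    if "call" in config.stages or "dmr" in config.stages:
        index = calling.BisulfiteIndex(genome)
        files = []
        for sample in samples:
            fq1 = outdir / f"reads_{sample}_1.fq"
            fq2 = outdir / f"reads_{sample}_2.fq"
            if not fq1.exists() or not fq2.exists():
                raise FileNotFoundError(
                    f"stage call: missing input {fq1} / {fq2} (run the simulate stage "
                    "or provide reads)"
                )
            raw = io.read_fastq_pairs(fq1, fq2)
            kept, qc_log = calling.qc_filter(raw)
            aligned = calling.bisulfite_map(
                kept, genome, max_mismatches=config.max_mismatches, index=index
            )
            retained, end_log = calling.enzyme_end_filter_and_mask(aligned, cut_sites, enz)
            calls = calling.call_cpg_methylation(retained, genome)
            calls_by_sample[sample] = calls
            conv = calling.estimate_conversion_rate(retained, genome)
            io.write_calls_tsv(calls, outdir / f"calls_{sample}.tsv", "call", phash)
            io.write_bedgraph(calls, outdir / f"calls_{sample}.bedgraph", "call", phash)
            files += [f"calls_{sample}.tsv", f"calls_{sample}.bedgraph"]
            manifest["metrics"][f"qc_{sample}"] = qc_log
            manifest["metrics"][f"aligned_pairs_{sample}"] = len(aligned)
            manifest["metrics"][f"end_filter_{sample}"] = end_log
            manifest["metrics"][f"conversion_rate_{sample}"] = (
                None if conv != conv else round(conv, 6)
            )
        manifest["outputs"]["call"] = files

    if "dmr" in config.stages:
        regions = [e for e in all_elements if e.element_class in ("CGI", "PROMOTER")]
        counts_a = stats.region_counts(calls_by_sample["A"], regions)
        counts_b = stats.region_counts(calls_by_sample["B"], regions)
        shifted_ids = {r.id for r in shifted_regions}
        with open(outdir / "dmr.tsv", "w") as fh:
            fh.write(io.stage_header("dmr", phash))
            fh.write(
                "contig\tstart\tend\tid\tclass\tstatistic\tp_value\tdelta\tis_dmr\ttruth_shifted\n"
            )
            n_dmr = 0
            for ca, cb in zip(counts_a, counts_b):
                if not (ca.covered and cb.covered):
                    continue
                res = stats.chi_square_dmr(
                    ca, cb, config.p_threshold, config.delta_threshold
                )
                n_dmr += res.is_dmr
                r = res.region
                fh.write(
                    f"{r.contig}\t{r.start}\t{r.end}\t{r.id}\t{r.element_class}"
                    f"\t{res.statistic:.4f}\t{res.p_value:.3e}\t{res.delta:.4f}"
                    f"\t{int(res.is_dmr)}\t{int(r.id in shifted_ids)}\n"
                )
        manifest["metrics"]["dmr_count"] = n_dmr
        manifest["outputs"]["dmr"] = ["dmr.tsv"]

    if "dge" in config.stages:
        gene_ids = [g.gene_id for g in genes] or [f"gene_{i}" for i in range(200)]
        rows, truth_de = simulate.simulate_dge_counts(gene_ids, config.seed)
        lib_a = sum(r[1] for r in rows)
        lib_b = sum(r[2] for r in rows)
        results = stats.call_de_genes(
            rows, lib_a, lib_b, config.fdr_threshold, config.fold_threshold
        )
        with open(outdir / "dge.tsv", "w") as fh:
            fh.write(io.stage_header("dge", phash))
            fh.write("gene\tcount_a\tcount_b\ttpm_a\ttpm_b\tp_value\tq_value\tis_de\ttruth_de\n")
            for r in results:
                fh.write(
                    f"{r.gene}\t{r.count_a}\t{r.count_b}\t{r.tpm_a:.3f}\t{r.tpm_b:.3f}"
                    f"\t{r.p_value:.3e}\t{r.q_value:.3e}\t{int(r.is_de)}"
                    f"\t{int(r.gene in truth_de)}\n"
                )
        manifest["metrics"]["de_count"] = sum(r.is_de for r in results)
        manifest["outputs"]["dge"] = ["dge.tsv"]

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
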