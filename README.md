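# drrbs — double-enzyme RRBS design and analysis

Reduced representation bisulfite sequencing (RRBS) measures CpG methylation
at single-base resolution by digesting genomic DNA with MspI (C^CGG),
size-selecting the CpG-enriched fragments, and sequencing them after
bisulfite conversion.  Because MspI sites cluster in CpG islands, classical
single-enzyme RRBS (sRRBS) leaves CGI shores, introns and other
moderate-CpG regions largely uncovered.  Adding a second,
methylation-insensitive enzyme with no CpG in its recognition site — ApeKI
(G^CWGC) — fragments those regions too, and the resulting double-enzyme
strategy (dRRBS) substantially widens CpG coverage at similar cost per
informative CpG.

`drrbs` implements that strategy as a desk toolkit for people designing or
analysing RRBS experiments:

* **Design** — in silico digestion of any genome by any combination of
  enzymes from a user-extensible table (IUPAC-aware, both strands), size
  selection, and prediction of which CpG dinucleotides a given read layout
  (e.g. PE50/PE90) interrogates, aggregated per genomic element (CpG
  islands, 2 kb shores, promoters, introns, ...).
* **Simulation** — a fully seeded generator of mammalian-like genomes
  (CpG-depleted background, embedded islands), bimodal methylomes
  (island CpGs ~ Beta(2,18), background ~ Beta(8,2)), and directional
  paired-end bisulfite reads with incomplete conversion, sequencing error,
  an unmethylated lambda-like spike-in, and the end-repair fill-in artifact.
* **Analysis** — the RRBS calling chain: read QC (drop reads with >30% N or
  >10% bases under Q20), three-letter bisulfite alignment against C→T and
  G→A reference forms with unique-best placement, retention of pairs with a
  digestion site at an outer end, masking of the 2 (MspI) or 3 (ApeKI)
  fill-in bases at the reverse read's 5′ end, per-CpG methylation levels
  `M/(M+U)`, and conversion-rate estimation from the spike-in.
* **Statistics** — region-level differential methylation by Pearson
  chi-square on the 2×2 table of methylated/unmethylated counts with the
  dual rule *p* < 0.01 **and** |Δlevel| > 0.20; per-CpG methylome
  concordance (Pearson *r* at a depth cutoff); and digital gene expression
  with the Audic–Claverie exact test
  (p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)), evaluated in log
  space) at Benjamini–Hochberg FDR < 0.01 with a two-fold TPM change.

## Worked example

```python
from drrbs import (SimConfig, synthesize_genome, assign_methylome, simulate_reads,
                   digest_genome, size_select, default_enzymes, qc_filter,
                   bisulfite_map, enzyme_end_filter_and_mask, call_cpg_methylation,
                   estimate_conversion_rate, predict_covered_cpgs, PE50)
from drrbs.enzymes import merged_cut_sites
from drrbs.calling import FastqRead

panel = default_enzymes()
enzymes = {name: panel[name] for name in ("MspI", "ApeKI")}

# 1. synthesize a 200 kb genome with islands, a methylome, and reads
config = SimConfig(seed=7, genome_length=200_000, n_cgis=16, n_genes=10,
                   lambda_length=20_000)
genome, islands, genes = synthesize_genome(config)
truth = assign_methylome(genome, islands, seed=7)

# 2. in silico digestion + size selection, single vs double enzyme
chr1 = {"chr1": genome["chr1"]}
single = size_select(digest_genome(chr1, [panel["MspI"]]), config.size_window)
double = size_select(digest_genome(chr1, list(enzymes.values())), config.size_window)
cov_s = predict_covered_cpgs(single, PE50, chr1)
cov_d = predict_covered_cpgs(double, PE50, chr1)
n = cov_s.total_cpgs()
print(f"CpGs covered (PE50, 40-220 bp): MspI {100*cov_s.covered_count()/n:.1f}% "
      f"vs MspI+ApeKI {100*cov_d.covered_count()/n:.1f}% of {n}")

# 3. simulate bisulfite reads and run the calling chain
fragments = size_select(digest_genome(genome, list(enzymes.values())), config.size_window)
pairs = simulate_reads(genome, truth, fragments, config, enzymes)
reads = [(FastqRead(p.name, p.r1_seq, p.r1_qual), FastqRead(p.name, p.r2_seq, p.r2_qual))
         for p in pairs]
kept, qc_log = qc_filter(reads)
aligned = bisulfite_map(kept, genome)
cuts = merged_cut_sites(genome, list(enzymes.values()))
retained, _ = enzyme_end_filter_and_mask(aligned, cuts, enzymes)
calls = call_cpg_methylation(retained, genome)
conversion = estimate_conversion_rate(retained, genome)
print(f"read pairs: {qc_log['pairs_in']} simulated, {len(aligned)} uniquely aligned, "
      f"{len(retained)} with enzyme ends")
print(f"CpGs called: {len(calls)}; spike-in conversion rate: {conversion:.4f}")
```

Output:

```
CpGs covered (PE50, 40-220 bp): MspI 14.6% vs MspI+ApeKI 20.7% of 3167
read pairs: 3254 simulated, 3254 uniquely aligned, 3254 with enzyme ends
CpGs called: 992; spike-in conversion rate: 0.9940
```

The double digest covers ~1.4× the CpGs of MspI alone on this small genome
(the gain concentrates in shores and background, as intended by the
design), every simulated pair starts at a digestion site and so survives
the enzyme-end filter, and the spike-in estimate recovers the simulated
99.5% conversion within sampling error.

A command-line interface mirrors the stages (`drrbs design`, `simulate`,
`call`, `dmr`, `dge`, and config-driven `run`); see `drrbs --help`.

## Layout

| Module | Role |
| --- | --- |
| `drrbs.enzymes` | enzyme model, cut-site scanning, digestion, size selection |
| `drrbs.elements` | CpG island detection, shores, promoters, overlap queries |
| `drrbs.coverage` | read footprints, covered-CpG prediction, coverage reports |
| `drrbs.simulate` | genome/methylome/read generator and spike-in |
| `drrbs.calling` | QC, three-letter mapper, end filter + masking, CpG calls |
| `drrbs.stats` | chi-square DMRs, Pearson concordance, Audic–Claverie DGE |
| `drrbs.io` / `drrbs.pipeline` / `drrbs.cli` | formats, config-driven runs, CLI |

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
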