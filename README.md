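# protopep

Analysis toolkit for high-density peptide-array screens of primordial
RNA–peptide interactions.

Peptide arrays display *every* combinatorial peptide over a reduced
amino-acid alphabet as replicated spots, incubate the chip with a
fluorescently labelled 12-mer RNA homo-oligonucleotide (poly-A/U/G/C),
and read out per-spot fluorescence — brighter means more RNA bound.
`protopep` covers the complete downstream analysis of such screens for
researchers studying the origin of the genetic code and RNA–peptide
binding preferences:

* **Protocode model** — the partition of the canonical amino acids into
  dominant/recessive AU- and GC-protocodes and their combinatorial
  fusion to the standard genetic code via Watson–Crick transition
  mutations (A↔G, U↔C), fully validated against the SGC.
* **Library design** — exhaustive combinatorial peptide enumeration
  (e.g. all 4⁷ = 16,384 GPAR 7-mers), seeded subsampling, and
  replicated, randomized array layouts with serializable manifests.
* **Array I/O** — GenePix-results-style and plain-TSV photometric
  tables, joined with the manifest into an analyzable screen dataset,
  with per-(library, channel) summary statistics.
* **Fragment interaction scoring** — the core statistic. Every
  contiguous fragment m is scored by

      R_m = mean(I_m) / sd(I_m)

  where I_m are the fluorescence signals of all peptides containing m
  (sample sd, ddof = 1). Ranked fragments are arranged into cumulative
  signature columns (all 3…n-mers per column) with displacement and
  residue-composition analyses.
* **Sum properties** — charge, molecular weight, Kyte–Doolittle
  hydrophobicity and Pace–Scholtz helix propensity per peptide, for
  property-vs-intensity analyses.
* **Substitution scans** — single-position variant scans of a seed
  peptide (e.g. polyproline × {A,G,R}) as position × residue intensity
  matrices.
* **Synthetic screens** — a seeded generative model (channel baselines,
  planted multiplicative motif effects, lognormal noise) with presets
  emulating the AU and GC screens, so every stage is testable without
  the experimental data.

## Worked example

Simulate a GC-like screen (full GPAR + STCR 7-mer sublibraries, 2
copies, cytosine channel), score fragments of the dominant sublibrary
and scan the polyproline:

```python
from protopep import (build_screen_dataset, build_signature_table,
                      generate_scan, preset_paperlike, scan_matrix,
                      score_fragments, simulate_screen)

config = preset_paperlike("GC", seed=7, channels=["C12"])
ds = build_screen_dataset(config.design, simulate_screen(config))

scores, gated = score_fragments(ds, "C12", library_id="GC-dominant",
                                min_support=30)
print(build_signature_table(scores, top_n=5).to_wide())
```

```
3mer 3-4mer 3-5mer
 PPP   PPPR  RAAAA
 GPG   PPPP  RAGAG
 GRR   RPPP  GPGRR
 RPA   PPPG  RRRGA
 GGA   GPPP  GRAGA
```

The planted polyproline signature tops the 3-mer column; in the 3–4mer
column it is displaced by its own longer super-fragments (PPPR, PPPP,
RPPP, …), the short-by-long displacement this analysis is designed to
expose. The substitution scan recovers the planted position-4 alanine
bonus:

```python
result = scan_matrix(generate_scan("PPPPPPP", "AGR"), ds, "C12")
print(result.best_sequence, round(result.best_intensity, 1))
```

```
PPPAPPP 80986.7
```

The same stages are available from the shell:

```sh
protopep fuse-codes --out fusion.tsv
protopep simulate --preset GC --seed 7 --out sim.tsv --manifest-out manifest.tsv
protopep score-fragments --manifest manifest.tsv --intensities sim.tsv \
    --channel C12 --library GC-dominant --out scores.tsv
protopep substitution-scan --manifest manifest.tsv --intensities sim.tsv \
    --seed-peptide PPPPPPP --subs A,G,R --channel C12 --out scan.tsv
```

Every output is accompanied by a `<output>.run.json` manifest (seed,
parameters, input digests); identical seeds give byte-identical outputs.

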