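# gdgtproxy

Tools for evaluating whether Marine Group II (MG-II) *Euryarchaeota*
contribute cyclopentane-ring GDGT lipids to marine waters — and thereby
bias the TEX86 paleothermometer — from tabular lipid and qPCR data.

Archaeal glycerol dialkyl glycerol tetraethers (GDGTs) carry 0–4
cyclopentane rings; ring abundance increases with growth temperature,
which the TEX86 index exploits as a sea-surface temperature (SST) proxy:

```
TEX86 = ([GDGT-2] + [GDGT-3] + [Cren']) / ([GDGT-1] + [GDGT-2] + [GDGT-3] + [Cren'])
SST (°C) = 68.4 · log10(TEX86) + 38.6
```

The calibration presumes a purely thaumarchaeotal GDGT source. This
package implements the full screen for a second, euryarchaeotal source:

- **Indices** — TEX86, ring indices RI₁ (crenarchaeol-weighted) and RI₂
  (crenarchaeol replaced by GDGT-4, isolating non-thaumarchaeotal rings),
  Methane Index, %GDGT-2, BIT and compound ratios, with explicit
  undefined markers on zero denominators.
- **Screening** — calibrated temperatures; deviation ΔRI from the global
  core-top parabola `RI = 3.32·TEX86² − 0.77·TEX86 + 1.59` (±0.3 zone);
  advisory QC flags (BIT > 0.2, GDGT-2/Cren > 0.4, MI > 0.5,
  GDGT-0/Cren > 2, %GDGT-2 > 45).
- **Statistics** — `RingEnrichmentModel`: an OLS screen of each lipid
  variable, per lipid pool (CL / total-IPL / phospho-IPL), against the
  [MG-II 16S]/[Archaea 16S] qPCR gene-copy ratio; group summaries, Welch
  tests, SPM–sediment station pairing.
- **Simulation** — a two-endmember (Thaumarchaeota + MG-II) mixing
  generator with compositional (Dirichlet) and lognormal qPCR noise, for
  validation and power analysis.
- **Data** — CSV/TSV readers with column-mapping schemas, and a packaged
  26-sample estuarine-transect table (18 water-column + 8 sediment
  samples, with qPCR data on 12) to demonstrate the full analysis.

See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
import gdgtproxy as g

ds = g.load_table1_fixture()                     # packaged transect table
fit = g.RingEnrichmentModel(ds, y_variables=("ri2",)).fit()
print(fit.summary())
```

```
Ring-enrichment regression screen
  x: [MG-II 16S]/[Archaea 16S] gene copy ratio
  samples with gene data: 12

     CL_R2  CL_P  total_IPL_R2  total_IPL_P  phospho_IPL_R2  phospho_IPL_P
ri2   0.49  0.01          0.51         0.01            0.72           0.00
```

Read: across the 12 water-column samples with gene data, the
crenarchaeol-free ring index RI₂ rises with MG-II enrichment in every
lipid pool, most strongly in the phospho-IPL pool (R² = 0.72,
p < 0.01) — the pool that best reflects living biomass. That is the
expected signature if MG-II produce ringed GDGTs *in situ*.

Group contrasts come from the same dataset:

```python
for gs in g.group_summary(ds, "water_type", "gene_ratio"):
    print(gs.group_key[0], gs.n, round(gs.mean, 4))
# mixing 6 0.2571   <- estuarine mixing zone: MG-II hot spot
# river  2 0.0001
# sea    4 0.1025
```

And the simulator closes the loop — a synthetic transect with known
MG-II input reproduces the same regression structure and shows the
induced TEX86 cold bias:

```python
sim = g.simulate_transect(g.TransectConfig(n_samples=50, seed=1))
print(g.regression_screen(sim).summary())
```

A command line mirrors the library: `gdgtproxy run` (full pipeline →
TSV report bundle), `gdgtproxy fixture`, `gdgtproxy simulate`,
`gdgtproxy indices`.

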