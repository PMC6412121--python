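# silnas

Site-specific RNA modification stoichiometry from LC-MS, using
stable-isotope-labeled internal standards.

## The problem

Spliceosomal snRNAs (U1, U2) carry 2′-O-methylations and pseudouridines at
defined positions, and the *fraction of molecules modified at each site* —
the stoichiometry — is biologically regulated. It can be measured by mass
spectrometry: digest the RNA with a base-specific ribonuclease, and each
modification changes the mass (+CH₂ for a methyl), the cleavage pattern
(2′-O-methyl removes the 2′-OH that RNase T1/A need, extending the product
past the blocked site), or only the retention time (pseudouridine is
mass-silent but chromatographically separable). Mixing the cellular RNA
~1:1 with an unmodified in-vitro transcript made from ¹³C-labeled NTPs
(¹³C₁₀-guanosine for RNase T1 digests; ¹³C₉-cytidine/-uridine for RNase A)
puts a heavy internal standard next to every light fragment.

This package implements the desk side of that workflow for people who run
or evaluate such experiments:

- **`silnas.rna`** — RNA molecules with 5′/3′ end chemistry (including the
  TMG cap), modification types, label schemes; FASTA and site-table readers.
- **`silnas.digestion`** — modification-aware in-silico RNase T1/A
  digestion with missed-cleavage enumeration, and guide-directed RNase H
  splitting (5′-phosphate / 3′-OH products).
- **`silnas.masses`** — elemental composition, monoisotopic mass,
  negative-mode m/z with an acquisition window (m/z 480–1980), heavy-label
  shifts, and c/y/w/a−B MS2 product-ion ladders.
- **`silnas.identify`** — a theoretical search space (≤1 variable methyl
  per fragment, fixed known sites exempt), MS1 matching at ±5 ppm, MS2
  ladder scoring at ±20 ppm, and ambiguity resolution for base-composition
  isobars such as CACUCCG₆₉₋₇₅ vs ACCCCUG₈₅₋₉₁.
- **`silnas.quantify`** — the two estimators. Isotope dilution:
  `f = 1 − L/(k·H)` with the mixing correction `k` averaged over ~10
  unmodified light/heavy fragment pairs. Peak area:
  `f = ΣA_mod / (ΣA_mod + ΣA_unmod)` from extracted-ion chromatograms,
  summing isomeric modified species. Plus per-site mean ± SEM and Tukey
  comparisons across conditions.
- **`silnas.simulate`** — a synthetic LC-MS generator whose default
  scenario encodes the reference U1/U2 site set (70Am; 11Gm, 12Gm, 19Gm,
  25Gm, 30Am, 34Ψ, 40Cm, 47Um, 61Cm, the TMG caps) with control and two
  knockdown conditions, so the whole pipeline is testable without any raw
  instrument files.
- **`silnas.pipeline` / the `silnas` CLI** — feature finding →
  identification → quantification → a publication-style report.

## Worked example

Simulate the default benchmark (3 replicates × 3 conditions) and quantify
every site with both estimators:

```python
from silnas import default_scenario, simulate, run_quantification

scenario = default_scenario()
result = simulate(scenario)
estimates, reports, summary = run_quantification(
    scenario, result.peaklists, result.spectra
)
print(summary[["molecule_id", "position", "mod_type", "method",
               "control_mean_pct", "control_sem_pct",
               "knockdown-1_mean_pct", "knockdown-1_p"]].round(3).head(8))
```

```
molecule_id  position    mod_type    method  control_mean_pct  control_sem_pct  knockdown-1_mean_pct  knockdown-1_p
         U1         1 2'-O-methyl peak_area           100.000            0.000               100.000            NaN
         U1        70 2'-O-methyl    silnas            79.754            0.945                18.833          0.000
         U1        70 2'-O-methyl peak_area            79.593            0.987                23.641          0.000
         U2         1 2'-O-methyl peak_area            99.318            0.225                99.310          0.999
         U2        11 2'-O-methyl peak_area            95.526            0.694                95.412          0.984
         U2        12 2'-O-methyl peak_area            96.366            0.714                96.281          0.993
         U2        25 2'-O-methyl    silnas            97.657            1.139                31.329          0.000
         U2        25 2'-O-methyl peak_area            97.823            0.992                33.816          0.000
```

Each row is one site × estimator: the U1 70Am site sits near 80% modified
in the control and collapses below 25% under knockdown (Tukey p vs control
≈ 0), while the cap and the 11/12Gm sites are unchanged — and the two
independent estimators agree within their replicate SEMs. The same run is
available from the shell:

```bash
silnas simulate --seed 17 -o fixtures/
silnas quantify --fixtures fixtures/ -o report.tsv
```

## Limitations

The simulator emulates centroided negative-mode MS1 peak lists with
Gaussian elution profiles and lognormal intensity noise; it does not model
isotope envelopes, chromatographic physics, or instrument raw formats (a
minimal mzML reader is provided for interoperability). See
`docs/methods.md` for the full model description and numerical choices.
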