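# napsri

Retention-time indexing for reversed-phase LC–MS metabolomics using
N-alkylpyridinium-3-sulfonate (NAPS) reference standards.

## The problem

Accurate mass alone cannot tell isomers apart, and retention times — the
obvious orthogonal evidence — are system properties: dead volume, dwell
volume, gradient mixing and flow rate shift them so strongly that RTs from
one instrument are useless on another. Gas chromatography solved this long
ago with retention indices against a homologous alkane series (the Kovats
convention). NAPS bring the same idea to reversed-phase LC–MS: a C1–C20
homologous series of zwitterionic standards with pH-independent retention,
detectable in both ESI polarities ([M+H]+ / [M+HCOO]−, diagnostic fragment
[C5H6NO3S]+ at m/z 160.0063), co-injected with the sample.

The n-carbon homolog defines retention index RI = 100·n. An analyte's RI is
obtained by interpolating its RT between the bracketing anchors:

    RI = RI₀ + (RI₁ − RI₀) · (RT − RT₀) / (RT₁ − RT₀)

(linear method; natural-cubic and Akima splines are available). The linear
map is invariant under affine warps of the RT axis, which is why indices
transfer across instruments while raw RTs do not.

`napsri` is for metabolomics practitioners who want to build RI libraries
from standard runs, convert feature tables to RIs, annotate features by
combined m/z + RI matching, and check the ion suppression the co-injected
standards cause — plus a gradient-elution simulator (linear-solvent-strength
retention model) so every part of the workflow can be exercised and tested
without instrument data.

## Worked example

```python
from napsri import calibration as cal, examples
from napsri.annotation import MatchParams, match_mz, match_mz_ri
from napsri.chem import naps_mz_table

# reference m/z values of the first NAPS homologs
print(naps_mz_table((1, 4), ["[M+H]+"]).to_string(index=False))

# calibration from bracketing injections (average policy), then indexing
before = [(4, 1.02), (5, 1.31), (6, 1.95), (7, 3.05), (8, 4.40)]
after  = [(4, 1.06), (5, 1.35), (6, 2.01), (7, 3.11), (8, 4.48)]
model = cal.fit(cal.make_anchors(before, after, policy="average"), method="linear")
iv = model.rt_to_ri(2.50)
print(f"RT 2.50 min -> RI {iv.ri_rounded} "
      f"(extrapolated={iv.extrapolated}, below_usable={iv.below_usable})")

# isomer disambiguation: m/z 139.0389 at RI 513 vs the three C7H6O3 isomers
feat, lib = examples.isomer_feature(), examples.isomer_library(system=1)
params = MatchParams(mz_tol=0.005, ri_tol=10.0)
print(match_mz(feat, lib, params)[["compound_id", "delta_mz", "delta_ri"]])
print(match_mz_ri(feat, lib, params)[["compound_id", "delta_mz", "delta_ri"]])
```

Output:

```
 n_carbons  ri adduct polarity         mz  low_retention
         1 100 [M+H]+      pos 174.021941           True
         2 200 [M+H]+      pos 188.037591           True
         3 300 [M+H]+      pos 202.053241           True
         4 400 [M+H]+      pos 216.068891          False

RT 2.50 min -> RI 647 (extrapolated=False, below_usable=False)

          compound_id  delta_mz  delta_ri
4-Hydroxybenzoic acid -0.000071       2.0
3-Hydroxybenzoic acid -0.000071     -48.0
       Salicylic acid -0.000071     -48.0

          compound_id  delta_mz  delta_ri
4-Hydroxybenzoic acid -0.000071       2.0
```

The m/z window (0.005 Da) matches all three hydroxybenzoate isomers — they
share the formula C7H6O3, so mass cannot separate them. Adding the RI
filter (10 index units) keeps only 4-hydroxybenzoic acid, whose library RI
(511) sits 2 units from the observed 513; the other two are 48 units away.
The C1–C3 homologs are flagged `low_retention`: they elute in or near the
void volume, so robust indices start above RI 300.

## Command line

Every step is also a `napsri` subcommand operating on CSV/JSON:

```
napsri simulate --seed 7 --out-dir study/
napsri calibrate --naps-before study/naps_F0.30_r1.csv --method linear --out cal.json
napsri index --calibration cal.json --features study/run_F0.30_r1.csv --out indexed.csv
napsri build-library --runs r1.csv,r2.csv,r3.csv --calibrations c1.json,c2.json,c3.json --out library.csv
napsri annotate --library library.csv --features indexed.csv --mode mz+ri --out annotations.csv
napsri suppression --spiked study/matrix_spiked_1-20.csv --unspiked study/matrix_unspiked.csv \
    --naps-apexes study/naps_matrix_apexes.csv --dilution 1:20 --out suppression.csv
napsri naps-mz --n-range 1:20 --adducts "[M+H]+" --polarity pos --out naps_mz.csv
```

See `docs/methods.md` for the model, the simulator's assumptions and the
numerical choices.

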