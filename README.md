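# mechanospec

Co-localized Brillouin–Raman microspectroscopy analysis for 3-D tissue
models (tumor spheroids and organoids), with a synthetic phantom generator
for end-to-end validation.

Brillouin microscopy maps viscoelasticity at sub-cellular resolution: the
Brillouin shift ν_B (GHz) and linewidth Γ_B (FWHM, GHz) of light
inelastically scattered by acoustic phonons relate to the complex
longitudinal modulus M = M′ + iM″ through

    M′ = ρ λ² ν_B² / (4 n²),    M″ = ρ λ² ν_B Γ_B / (4 n²),

with ρ the mass density, n the refractive index and λ the excitation
wavelength. The Brillouin loss tangent BLT = Γ_B/ν_B = M″/M′ is independent
of (n, ρ, λ). Because ν_B and Γ_B alone cannot tell stiff protein from a
lipid droplet with different optics, the analysis pairs each Brillouin
point with a co-located Raman spectrum, clusters the Raman spectra into
biochemical groups (k-means, Euclidean metric; cluster count by Silhouette
/ Davies–Bouldin / Calinski–Harabasz majority vote), and compares ν_B, Γ_B
and BLT across groups with unequal-variance statistics (Welch t/ANOVA,
Games–Howell post-hoc).

The package implements the full chain:

- **`mechanospec.synthetic`** — phantom spheroid/organoid maps: raster
  Brillouin maps (50 × 50, 2 µm step) and co-localized Brillouin+Raman
  line maps, with per-class ground truth and a two-component noise model
  calibrated against sucrose-standard repeatability.
- **`mechanospec.brillouin`** — Lorentzian band fitting, per-spectrum
  frequency calibration from the methanol reference pair (ν_ref = 3.81
  GHz), instrumental-linewidth correction (FWHM subtraction), moduli/BLT.
- **`mechanospec.raman`** — asymmetric-least-squares baseline removal,
  area normalization, fingerprint-region cropping.
- **`mechanospec.clustering`** — k-means, cluster-count selection,
  silhouette analysis, centroid differences, off-target (medium/blank)
  cluster discard.
- **`mechanospec.stats`** — per-cluster medians, Welch omnibus tests,
  Games–Howell pairwise comparisons, shift–width correlation, 50 MHz
  histograms.
- **`mechanospec.pipeline` / CLI** — the end-to-end run with provenance
  and per-stage logging.

See `docs/methods.md` for the model, the calibration procedure and known
limitations.

## Worked example

Run the full pipeline on a simulated dataset of ten co-localized line maps
(500 points) through a U87-like spheroid phantom:

```sh
mechanospec run --out report/ --seed 1
# k_opt = 3; 3 clusters retained; report in report/
```

`report/medians.csv` then contains (abridged):

```
# mechanospec 0.1.0
# seed: 1
cluster,n,median_nu_B,median_gamma_B,median_blt,...
0,292,5.3637,0.4366,0.0816,...
1,122,5.3820,0.5100,0.0954,...
2, 86,5.3960,0.5979,0.1105,...
```

Three biochemical clusters were selected by the criterion vote. Cluster 0
(dominant, protein/cytoplasm-like Raman centroid) has median ν_B =
5.364 GHz and corrected Γ_B = 0.437 GHz; cluster 1 (protein+glycogen,
865/942 cm⁻¹ bands in the centroid) and cluster 2 (lipid, 1440 cm⁻¹
dominated) sit at higher shift and markedly higher linewidth — the
generating phantom classes were (5.36, 0.44), (5.38, 0.51) and
(5.39, 0.59) GHz, so the pipeline recovers each class's parameters to a
few MHz. `report/tests.json` holds the Welch ANOVA (here P < 10⁻⁶ for
both ν_B and Γ_B) and the Games–Howell pairwise table;
`report/criteria.csv` the per-k criterion scores; `report/stage_log.json`
the point counts entering and leaving every stage.

Stages can also be run individually:

```sh
mechanospec simulate --kind organoid_line --seed 7 --out map.h5
mechanospec fit-brillouin --in map.h5 --out fits.csv
mechanospec prep-raman --in map.h5 --crop 600 1800 --out raman.h5
mechanospec cluster --in raman.h5 --k-range 2 8 --seed 7 --out clus/
mechanospec stats --fits fits.csv --labels clus/labels.csv --out report/
```

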