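# brainmech

Two-scale brain biomechanics analysis in Python:

* **MRE branch** — simulate steady-state plane shear waves (1.0 kHz) in a
  labeled viscoelastic phantom, encode them into wrapped motion-encoding
  gradient (MEG) phase volumes (4 phase offsets, ±x/±y/±z polarities),
  reconstruct the complex harmonic displacement field (polarity
  differencing → slice-wise phase unwrapping → temporal harmonic
  extraction), and invert it by algebraic Helmholtz inversion (AHI) to
  storage modulus G′, loss modulus G″ and shear stiffness |G\*| maps with
  per-ROI statistics.
* **AFM branch** — synthesize spherical-indenter force curves from the
  Hertz contact law (R = 6 µm, k = 0.1 N/m, ν = 0.5) with cantilever
  compliance, detect contact points by two-regime residual minimization,
  fit per-cell Young's moduli with the linearized closed-form estimator,
  and compare cell-type groups with a Welch two-sample t-test.

Everything downstream is testable without external data: the
`synthetic_data` module is a first-class, seeded generator whose outputs
carry their ground truth.

## Layout

```
src/brainmech/
  synthetic_data.py    phantoms, wave fields, MEG encoding, force curves
  phase_processing.py  wrapped phase -> complex displacement field
  inversion.py         AHI, modulus maps, ROI statistics
  afm_hertz.py         contact detection, Hertz fits, group comparison
  io_cli/              NIfTI/CSV formats, YAML config, pipeline, CLI
```

## CLI

```sh
brainmech run          --config demo.yaml --out out/       # full pipeline
brainmech simulate-mre --config demo.yaml --out out/
brainmech invert       --in out/ --config demo.yaml --out maps/ \
                       --laplacian modified_wavenumber --rho 1000
brainmech simulate-afm --config demo.yaml --out afm/
brainmech fit-afm      --curves afm/curves --probe probe.yaml --out results/
brainmech compare      --group-a results_a/cell_results.csv \
                       --group-b results_b/cell_results.csv
brainmech --version
```

A minimal config (strictly validated; unknown keys and missing seeds are
rejected):

```yaml
schema_version: 1
mre:
  phantom:
    grid_shape: [96, 96, 10]
    voxel_size_mm: [0.2, 0.2, 0.3]
    regions:
      - {label: 1, storage_pa: 8070, loss_pa: 3200}
    seed: 1
  inversion: {laplacian: modified_wavenumber}
afm:
  groups:
    - {name: neuron,    mean_pa: 470.88, sd_pa: 111.8, n_cells: 40, seed: 1}
    - {name: astrocyte, mean_pa: 681.13, sd_pa: 89.5,  n_cells: 40, seed: 2}
```

`brainmech run` writes acquisitions/maps as NIfTI, curves as CSV, reports
as CSV/JSON, plus a `manifest.json` with sha256 hashes — runs are
byte-reproducible under a fixed config.

## Conventions worth knowing

* SI units internally everywhere; kPa/nN appear only at reporting
  boundaries (`brainmech.inversion.kpa` and friends).
* Phase wraps to the half-open interval (−π, π].
* Waves are `u(r) = A p exp(−i k n·r)` with `k = ω√(ρ/G*)` taken as the
  principal root (Re k > 0, Im k ≤ 0), so amplitude decays along the
  propagation direction and `G* Δu = −ρω²u` holds exactly per region.
* The temporal harmonic uses the kernel `exp(−2πi t/N)` with factor 2/N;
  the decoder conjugates, making encode → reconstruct the identity.
* ROI dispersion is the sample SD (ddof = 1); group summaries report both
  SD and SEM.
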