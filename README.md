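# b2mq

Quantitative analysis of membrane-protein expression and its morphological
and electrophysiological consequences, built for studies of the
voltage-gated sodium-channel auxiliary β2 subunit (and proteins like it)
in adherent cells and cultured neurons. The package bundles the three
measurement families such a study needs, plus seeded synthetic-data
generators with full ground truth so every estimator can be validated
end to end:

* **TIRF membrane-expression quantification** (`b2mq.tirf`) — paired
  protein / membrane-reference (e.g. FM1-43) channels. Includes the
  intensity-difference map `D = F_β − F_M·⟨F_β⟩/⟨F_M⟩` (normalized over a
  5×5 µm² central ROI), radial intensity profiles along auto-placed 10 µm
  segments crossing the cell edge with five-sample **border-to-center
  ratios**, and the expression index `R = (S − N)/N` from 3×3 µm² ROIs.
* **Process morphometry** (`b2mq.morphometry`) — detection of
  filopodia-like processes (width < 1 µm) by skeleton decomposition,
  geodesic length measurement, length binning into <4 / 4–8 / >8 µm
  groups, protrusion counts per 20 µm dendrite selection, and the
  **branching-area index** (percent of the non-soma field occupied by
  thresholded branches after high-pass and median filtering).
* **Whole-cell voltage-clamp analysis** (`b2mq.ephys`) — P/4 leak and
  capacitance subtraction, passive parameters (Ra, Rm, Cm) from the RC
  transient, access-resistance-corrected conductance, and **Boltzmann
  activation fits** `G_M/G_0 = 1/(1+exp((V½ − V_m)/s))` with the gating
  charge `q_g = k_BT/(e·s)`, specific conductance (nS/pF) and the
  Ra ≤ 15 MΩ quality filter.
* **Group statistics** (`b2mq.stats`) — mean ± SEM summaries, two-tailed
  Student/Welch t-tests at α = 0.05, and raw + rounded fold changes.
* **Synthetic data** (`b2mq.synthetic`) — TIRF cell pairs in which both
  channels share one membrane-proximity/adhesion field while only the
  protein channel carries border-enriched expression; neuron arbors with
  dendrite-specific filopodia-like protrusions; voltage-clamp sweeps from
  a passive RC cell plus a Boltzmann-activated sodium conductance, P/4
  subpulses included. Deterministic given a seed, with ground truth.

## Worked example

```python
from b2mq.synthetic import TirfCellSpec, VcCellSpec, generate_tirf_pair, simulate_vc
from b2mq import ephys
from b2mq.pipeline import cell_mean_ratio

# peripheral enrichment of a membrane protein, discounting adhesion
beta, fm, truth = generate_tirf_pair(TirfCellSpec(enrichment_rho=1.34, seed=1))
ratio = cell_mean_ratio(beta, fm, truth, n_segments=10, seed=1)
print(f"border-to-center ratio (10 segments): {ratio:.3f}")

# one voltage-clamped cell through the full activation analysis
cell = VcCellSpec(V_half_mV=-18.56, slope_mV=6.29, Gmax_nS=18.0,
                  Ra_MOhm=9.0, Cm_pF=11.0, seed=1)
res = ephys.analyze_cell(simulate_vc(cell), e_rev_mV=65.0)
print(f"Ra = {res.passive.Ra_MOhm:.2f} MOhm, Cm = {res.passive.Cm_pF:.2f} pF")
print(f"V0.5 = {res.fit.v_half_mV:.2f} mV, s = {res.fit.slope_mV:.2f} mV/e-fold, "
      f"q_g = {res.fit.q_gating:.2f} e")
print(f"specific conductance = {res.specific_nS_per_pF:.2f} nS/pF")
```

prints

```
border-to-center ratio (10 segments): 1.335
Ra = 9.04 MOhm, Cm = 10.99 pF
V0.5 = -18.49 mV, s = 6.24 mV/e-fold, q_g = 4.07 e
specific conductance = 1.65 nS/pF
```

The border-to-center ratio of 1.335 recovers the generating peripheral
enrichment of 1.34 from the noisy protein channel; the fitted
half-activation voltage and slope recover the generating Boltzmann
parameters (−18.56 mV, 6.29 mV/e-fold) within the per-cell noise, and the
passive fit returns the cell's true access resistance and capacitance.

## Command line

`b2mq` exposes the stages as subcommands:

```bash
b2mq synth --kind tirf --seed 1 --out data/cell1     # images + truth sidecar
b2mq diffmap data/cell1/beta.tif data/cell1/fm.tif --out diff.tif
b2mq radial data/cell1/beta.tif data/cell1/fm.tif --seed 1 --out ratios.csv
b2mq ephys sweeps.csv protocol.json --erev 65 --out fit.json
b2mq run --seed 1 --out report/                      # end-to-end synthetic run
```

A fixed seed makes `b2mq run` byte-for-byte reproducible.

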