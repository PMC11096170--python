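# Methods

## Problem and model

The package estimates two voxel-wise material properties needed for proton
dose calculation from multi-sequence MR intensities:

* **mass density** ρ (g/cm³), and
* **relative stopping power** RSP, the ratio of a material's proton stopping
  power to that of water.

The core model is a tabular fully connected network applied independently at
each voxel. An input voxel is the vector of water-normalized intensities of
the configured sequences (2–4 channels depending on schema); the output is a
single scalar (ρ or RSP). Density and RSP are trained as two separate
single-output networks, because their losses are defined independently; a
joint two-output variant is available behind the `joint=True` flag of
`train_bundle` for users who prefer weight sharing.

Architecture and optimization defaults (all in `FCNNConfig`):

| parameter      | default | notes                                             |
|----------------|---------|---------------------------------------------------|
| hidden layers  | 9       | best of the 5–11 range in the calibration studies |
| width          | 80      | nodes per hidden layer                            |
| block order    | linear → layer norm → ReLU | final layer linear, no activation |
| optimizer      | Adam, lr 1e-3 | mini-batch MSE                              |
| batch size     | 1000    |                                                   |
| max epochs     | 500     | trained to completion, no early stopping          |
| epochs used    | 300     | prediction uses this parameter snapshot           |
| initialization | uniform fan-in, seeded | `U(±1/√fan_in)` per layer          |

The `epochs_used` snapshot guards against late-epoch overfitting without
making the stopping point data-dependent: training always runs to
`max_epochs`, the full train/validation loss history is recorded, and
inference uses the parameters saved at `epochs_used`. The validation
partition is monitoring-only — it never influences updates or stopping.

The network is implemented directly on numpy (forward, layer-norm backward
and Adam in ~200 lines). A voxel-wise k→1 regression at these widths is small
enough that a framework adds no capability, and the closed implementation
makes bit-exact reproducibility straightforward: weights, shuffling and
optimizer state all derive from one seeded generator, so identical seed and
data give identical histories and predictions.

### Baselines

* **DECT empirical conversions**, applied to relative electron density ρₑ
  and effective atomic number Z_eff maps:
  ρ = −0.1746 + 1.176 ρₑ, and a four-branch RSP formula over half-open
  Z_eff intervals [0, 0.5), [0.5, 8.5), [8.5, 10), [10, ∞) with factors
  1, (1.1114 − 0.0148 Z_eff), 0.9905, (1.1117 − 0.0116 Z_eff) times ρₑ.
  Outputs are not clipped; the affine density fit can go negative at very
  low ρₑ, and evaluation reports count negative predictions rather than
  truncating them.
* **Linear baseline**: ordinary least squares of the target on the single
  T1-D-P-W channel. One MR channel cannot separate tissues whose T1 signal
  ties (e.g. fat is mid-bright where its density is low), so this baseline
  bounds what a non-learned single-channel conversion can do.

## Supporting physics

* Mean Z/A of a mixture: Σ wᵢ Zᵢ/Aᵢ; relative electron density
  ρₑ = ρ · (Z/A)/(Z/A)_water with water Z/A computed from the H 11.19% /
  O 88.81% composition (0.55509).
* **Bragg additivity**: ln I = Σ(wᵢZᵢ/Aᵢ ln Iᵢ)/Σ(wᵢZᵢ/Aᵢ). Elemental
  I-values default to ICRU condensed-phase recommendations (H 19.2, C 81,
  N 82, O 106, Na 149, P 173, S 180, Ca 191 eV) and are swappable: the
  tabulated mixture I-values in the packaged measurement table sit 2–8%
  above plain elemental additivity (the tabulation's convention — e.g.
  whether water entered as a compound with its own I — is not recoverable),
  so physics cross-checks are tolerance-based (5% for soft tissue and
  spongiosa, 10% for the hydroxyapatite-rich mix) rather than exact.
* **Bethe-ratio RSP** at kinetic energy T (default 150 MeV):
  RSP = ρₑ·[ln(2mₑc²β²/(I(1−β²))) − β²]/[same with I_w], I_w = 75 eV,
  proton rest energy 938.272 MeV, electron rest energy 0.511 MeV (CODATA).
  Shell and density-effect corrections are neglected — adequate at
  therapeutic energies for these materials, as the agreement with the
  measured RSP column (within 0.5–4%) confirms.
* **Effective atomic number**: power-law mixture rule with exponent
  m = 3.1 (a common spectral-CT convention; configurable).

## Synthetic study

The simulator emulates the calibration bench: a cylindrical deionized-water
container of 84.1 mm radius and 254 mm height with rectangular
57 × 57 × 129 mm³ tissue-substitute inserts, voxelized at 1 mm isotropic
(axis order slice/row/column, voxel centers at integer coordinates,
half-open insert intervals so a 57 mm box spans exactly 57 voxels). Seven
inserts do not fit one cross-section, so the default study uses two
cylinders (4 + 3 inserts on a 2×2 grid whose corners stay inside the
radius). All channels are born on one grid: registration is out of scope.

**What is emulated and what is not.** Per-tissue nominal MR signals are not
physically simulated — no public per-tissue intensity values exist for these
custom phantoms — so the default signal table encodes the qualitative
contrasts reported for the real sequences (adipose bright on the Dixon fat
channel and dark on STIR; the 45% hydroxyapatite mix bright on T1-Dixon,
dark on T2-STIR, brightest on ZTE; mineral-bearing mixes elevated on ZTE)
with numeric stand-ins separated by several noise standard deviations.
Noise is additive Gaussian with σ = water-signal/SNR and SNR 30 per sequence
(the floor observed on the real acquisitions; a Rician magnitude option
exists for realism). DECT material decomposition is emulated directly as
per-tissue ρₑ (from composition and measured density) and Z_eff maps with
multiplicative Gaussian noise at the published mean decomposition errors
(0.8% and 2.9%). Consequently, passing tests demonstrate that the method
recovers a voxel-wise signal→property mapping under realistic noise and a
strict train/application split — they do not certify accuracy on real
scanner data, where intra-tissue heterogeneity, bias fields, registration
residuals and sequence-dependent nonlinearities are all absent from the
simulation.

## Protocol

* **Half-and-half slices**: training samples come only from slices
  [0, ⌊S/2⌋), application/evaluation only from [⌊S/2⌋, S); an odd slice
  count gives the extra slice to the application half (the midpoint
  convention is the package's choice).
* **VOI sampling**: a circular VOI of radius 15 voxels at each insert's
  in-plane centroid, intersected with the insert's own label mask; the
  stated per-phantom voxel count (default 24,000, matching the published
  matrix sizes 168,000 × 3 for the three-channel seven-phantom schema and
  120,000 × 4 for the four-channel five-phantom schema; 48,000 with
  all-slices policy for the patient-style 336,000-row matrices) is drawn
  uniformly without replacement across the allowed slices. The published
  description ties 24,000 to "each slice", which is arithmetically
  inconsistent with the printed totals; the per-phantom reading is the one
  that reproduces them and is what this package implements.
* **75/25 split** of training rows into fit/validation, stratified per
  phantom, seeded.
* Water normalization divides each channel by the mean signal over the
  water label (or a user-supplied mask on real data); the water region of a
  normalized channel has mean 1 to ≤1e-9.

## Evaluation

APE and MAPE as defined above; the ± column is the **population standard
deviation of per-voxel APE** (the tabulated convention behind published ±
columns is not stated; voxel-level SD is this package's documented choice,
and slice-level aggregation can be built from the provenance columns).
Reports are tidy CSV/JSON plus a phantom × model text table. Line profiles
use nearest-voxel lookup, not interpolation, matching voxel-indexed profile
figures.

## Problem sizes used in the shipped checks

The study-scale test suite trains the default 9 × 80 architecture for 100
epochs on 2,000 sampled voxels per phantom (1,500 after the 75/25 split) and
evaluates on 2,000 held-out application-slice voxels per phantom — sizes at
which the optimization is fully converged for this problem (loss plateaus
well before epoch 100) while keeping a full four-model, two-noise-level run
in the minutes range on a single CPU. The matrix-assembly checks run at the
full published counts (24,000/48,000 per phantom), since extraction is cheap.
Expected outcomes at these sizes: per-phantom held-out MAPE ≈ 0 (noiseless)
and ≤ 0.5% at SNR 30 for both targets and both phantom schemas, versus
roughly 1% for the DECT empirical baseline and 5–30% for the single-channel
linear baseline.

## Numerical and design notes

* Layer-norm epsilon 1e-5; MSE gradients averaged over all batch elements.
* Ties/degeneracies: empty water mask, constant baseline channel,
  single-slice volumes, overlapping or out-of-container inserts, missing
  (tissue, sequence) signal entries and channel/schema mismatches all raise
  with the offending names rather than proceeding.
* The patient-style schema C is defined on (T1-D-P-W, T2-STIR) by default
  but the pair is explicit and configurable, since clinical datasets differ
  in which second channel is available; schema D appends the two
  DECT-surrogate channels (ρₑ, Z_eff) in place of learned synthetic-DECT
  images, which are out of scope.
* Volumes are NIfTI-1 (uncompressed) with spacing in the affine; tables are
  CSV; configs YAML; manifests JSON with sha256 checksums. No DICOM
  ingestion, no dose calculation, no Bloch/k-space simulation, no CT
  sinogram physics, no registration.

## Known limitations

* Synthetic contrasts are stand-ins; results on real scans are explicitly
  not claimed (see above).
* The tissue set spans ρ 0.936–1.417 g/cm³ — no lung-like or cortical-bone
  densities — so the learned mapping extrapolates poorly outside that range,
  and the linear baseline's failure is partly a consequence of deliberately
  non-monotone signal/density orderings in the default table.
* Bragg-additivity I-values reproduce the tabulated column only to a few
  percent (convention mismatch); the Bethe RSP check absorbs this by using
  the tabulated I directly.
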