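# bendscape

Analysis pipeline for quantifying how DNA-bending proteins — nucleoid-associated
proteins such as integration host factor (IHF) — reshape and bridge DNA, for
researchers combining single-molecule AFM imaging with molecular simulation.
Everything is exercisable on synthetic data with known ground truth, so each
stage can be validated end to end without instrument data.

## What it computes

- **AFM image analysis** (`bendscape.afm`): line-by-line flattening with a
  second-order surface fit and scar repair; height-threshold segmentation and
  skeleton tracing of individual DNA molecules; contour length, end-to-end
  distance and radius of gyration (R_g); one bend angle per molecule, θ,
  measured from 4-px (16 nm) arm vectors either side of a 3-px window around
  the highest point on the contour (the bound protein), with θ = 0° for
  straight DNA; zero-basis cluster volumes.
- **Bend-angle mixture statistics** (`bendscape.angles`): the distribution of
  θ for protein-incubated DNA is decomposed as

  n(θ) = N [ w₀ B(θ) + Σⱼ wⱼ 𝒩(θ; μⱼ, σⱼ) ],  w₀ + Σ wⱼ = 1,

  where the background shape B is a single Gaussian frozen on the bare-DNA
  sample and the modes 𝒩 are Gaussians truncated to [0°, 180°], fitted to the
  10° histogram by weighted least squares with Poisson errors; model order is
  chosen by reduced-χ² goodness of fit. Binding-mode proportions are the wⱼ
  renormalised over bound molecules. Kernel density estimates,
  two-sample Kolmogorov–Smirnov tests and reduced-χ² utilities included.
- **Trajectory geometry** (`bendscape.trajectory`): helix-axis contouring by
  base-pair-centre smoothing; projection onto the total-least-squares best-fit
  plane with a planarity percentage; the bend angle between vectors joining
  axis points 30 bp apart separated by a further 30 bp centred on the binding
  site; Kabsch-superposition RMSD; average-linkage agglomerative clustering of
  frames into binding modes; hydrogen-bond contact maps (donor–acceptor
  distance ≤ 3.5 Å and D–H···A angle ≥ 120°, per-residue occupancy capped
  at 1).
- **Free-energy reconstruction** (`bendscape.fes`): WHAM over umbrella-sampling
  windows → 1D potentials of mean force; linear coordinate remapping;
  plateau offset alignment; a 2D landscape F(x_L, x_R) built by linear
  interpolation between each arm's bound and held-away PMFs plus simple
  addition of energies; the probability landscape P = exp(−F/k_BT) and
  weighted state integration at 1 Å resolution, normalised to 100%.
- **Motif scanning** (`bendscape.pssm`): PSSM construction, log₂-odds scoring
  W_s = log₂(P(M)/P(B)), exact null p-values by dynamic-programming
  convolution, both-strand scanning with the stringent p ≤ 0.0002 cutoff or
  the permissive W_s ≥ 1 rule, and IUPAC consensus matching
  (WATCARNNNNTTR).
- **Synthetic data** (`bendscape.simulate`): 2D worm-like-chain molecules with
  optional three-state protein kinks, rendered AFM fields (tip PSF, scan-line
  offsets, noise, scars, globular artifacts) with machine-readable ground
  truth; exact Boltzmann sampling of umbrella windows from analytic
  potentials; labelled toy conformational ensembles with constructed
  hydrogen-bond geometry; background sequences with planted motifs.
- **Orchestration** (`bendscape.pipeline`, `bendscape` CLI): declarative
  multi-stage runs with seeds and machine-readable JSON reports.

## Worked example

`examples/02_bend_angle_mixture.py` draws 2000 bend angles from a 65%
naked-DNA background plus the three binding modes and refits them:

```
selected 3 modes over the background (chi2/nu = 1.98, p = 0.04)
background weight w0 = 0.657 (unbound molecules + thermal bending overlap)
  associated   : mean   74.3 deg, sd  7.6 deg, weight 0.103
  half-wrapped : mean  107.0 deg, sd  8.4 deg, weight 0.075
  fully wrapped: mean  139.5 deg, sd 31.7 deg, weight 0.165
proportions among bound molecules: 30% / 22% / 48%  (generator truth 32% / 27% / 41%)
```

The three mode means recover the planted 73°/107°/147° bending states; the
broad fully-wrapped mode is hardest to pin down (angles near 180° are
measured with large uncertainty, which the generator reproduces with its
σ = 30° width). The other examples cover field rendering → tracing
(`01`), umbrella sampling → landscape → state populations (`03`), trajectory
clustering and axis bend angles (`04`), and motif scanning (`05`); each
prints what the numbers mean as it runs.

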