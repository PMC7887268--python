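# bzrmd

Structural validation toolkit for transcription-factor–DNA complexes solved
with a crystallization-chaperone fusion, aimed at structural biologists who
need to show that what the crystal shows is not an artifact of crystal
packing. The motivating system is the plant BZR-family DNA-binding domain:
a homodimer whose DNA-recognition helices cross at an unusually large tilt
angle (~78°) compared with canonical bHLH transcription factors (50–65°),
solved as a maltose-binding-protein (MBP) fusion.

The package implements the complete downstream analysis chain:

- **Superposition / RMSD** — Kabsch least-squares rigid-body fitting with a
  fit-on / measure-on selection split: every trajectory frame is superposed
  on one selection (e.g. protein Cα) and RMSD is reported on others (e.g.
  DNA phosphorus), per frame and as mean ± SD.
- **Recognition-helix tilt angle** — helix axes fitted as the dominant
  principal axis of turn-averaged Cα positions, and the crossing angle
  θ = arccos |û_a · û_b| ∈ [0°, 90°], per structure or per frame.
- **Contact dissection** — hydrogen bonds (donor–acceptor ≤ 3.5 Å, D–H···A
  ≥ 120° when hydrogens exist), salt bridges (charged N···O ≤ 4.0 Å),
  van der Waals contacts (r₁+r₂+0.4 Å), water-mediated bridges, per-pair
  H-bond occupancy over trajectories, and chaperone–cargo interface reports
  grouped by cargo residue with per-chain mean B-factors.
- **Alchemical free energy** — the Bennett acceptance ratio (BAR): per
  adjacent λ-state pair, ΔF solves
  Σ_F f(u_F − C) = Σ_R f(u_R + C) with f the Fermi function and
  C = ΔF − ln(n_F/n_R); steps are summed over a uniform λ schedule
  (21 states = 19 intermediates) and combined in the thermodynamic cycle
  ΔΔG = ΔG(complex, 1→2) − ΔG(DNA, 1→2), with six-replicate mean ± SD.
  Positive ΔΔG means the base substitution weakens binding.
- **Synthetic data** — generators for ideal helices, helix pairs at exact
  crossing angles, noisy/fluctuating trajectories, hydrogen-bond toggle
  series, and harmonic-oscillator alchemy with analytic free energies; every
  generator records its ground truth so estimators are scored against exact
  bookkeeping.

## Worked example

Build a synthetic dimer with its recognition helices crossing at 78° and
measure the tilt angle back:

```
$ bzrmd simulate helix-pair --out-prefix demo --angle 78
$ bzrmd tilt --struct demo.pdb --helix-a A:1-12 --helix-b B:1-12
# crystal structure tilt angle: 78.00 deg
```

The helix ranges are given as `CHAIN:FIRST-LAST` in author numbering. A
measured value near 78° is the BZR regime; canonical bHLH dimers fall in
50–65°.

Generate a toy binding system (free-DNA leg flat, complex leg stiffening
k: 1 → 4, analytic ΔΔG = ½ ln 4 ≈ 0.6931 kT) and run the six-replicate
thermodynamic cycle:

```
$ bzrmd simulate binding --out-prefix bind --samples-per-state 2000 --seed 5
$ bzrmd ddg --complex bind_complex --dna bind_dna
...
# ddg mean 0.6929 kT, sd 0.0066 kT (n=6)
```

The estimate agrees with the analytic value within the replicate scatter,
and its positive sign reads as "the substitution weakens binding".

Other subcommands: `rmsd`, `hbonds`, `contacts`, `occupancy`, and `run`
(a config-driven pipeline over all stages; see `bzrmd run --help`).

## Scope

The package analyzes structures and trajectories and implements the
free-energy estimators; it does not run molecular dynamics. Quantities that
require microsecond explicit-solvent MD (trajectory RMSD values of a real
complex, MD tilt series, MD occupancy percentages, nucleotide ΔΔG values)
can be computed by these tools from user-supplied trajectories or sampled
energy tables, and are exercised here on synthetic systems with known ground
truth. See `docs/methods.md` for models, conventions and limitations.
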