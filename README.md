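# cgslab

Coarse-grained slab-coexistence simulations and condensate analysis for
intrinsically disordered and multidomain proteins, with optional
double-stranded DNA.

Many chromatin regulators -- the methyl-CpG-binding domain (MBD) family
(MeCP2, MBD2, MBD3) among them -- form biomolecular condensates by
liquid-liquid phase separation (LLPS), driven largely by electrostatic and
hydrophobic interactions of their disordered regions. `cgslab` is for
researchers who want to probe that physics at residue resolution: build
one-bead-per-residue chains (with folded domains held rigid), run Langevin
dynamics in the slab geometry so dense and dilute phases coexist in one box,
and quantify the result -- saturation concentrations, interface profiles,
residue-level contact maps, and two-component phase diagrams with tie
lines.

## Model

* **Energetics** (hydropathy-scale model, Urry ranking): the pair potential
  between beads i and j combines an Ashbaugh-Hatch term, whose attractive
  Lennard-Jones well is scaled by the mean hydropathy
  λ_ij = (λ_i + λ_j)/2 while the repulsive core is retained, with
  Debye-Hückel screened electrostatics
  U = 332.06 q_i q_j exp(-κr)/(80 r) kcal/mol; κ⁻¹ ≈ 10 Å at 100 mM salt.
* **Chains**: harmonic backbone bonds (r₀ = 3.8 Å); folded domains are
  rigid bodies built from template (e.g. Cα) coordinates; DNA is a
  two-bead-per-nucleotide duplex with -1 e per backbone bead.
* **Dynamics**: BAOAB Langevin, NVT, friction γ_i = m_i/τ (τ = 1000 ps),
  10 fs timestep, numba-compiled kernels, bit-reproducible per seed.
* **Analysis**: slab-centered density profiles fitted with
  ρ(z) = (ρ_d+ρ_l)/2 − (ρ_d−ρ_l)/2·tanh((|z|−z₀)/w); the dilute branch
  ρ_l is the saturation concentration C_sat. Contacts: two beads on
  different chains with r < 1.5·(σ_i+σ_j)/2.

See `docs/methods.md` for conventions, parameter provenance and known
limitations.

## Worked example

Generate a fully blocky K/E polyampholyte (a minimal diblock that phase
separates through electrostatic complementarity), assemble 8 chains in a
slab box, simulate 0.4 ns and extract the coexistence profile:

```bash
cgslab synth polyampholyte --length 30 --blockiness 1.0 --seed 0 -o blocky.fasta
cgslab seq-stats blocky.fasta
cgslab build --seq blocky.fasta --count polyampholyte_b1_s0 8 \
       --box 50 50 250 --seed 1 -o slab.json
cgslab simulate --topo slab.json --steps 40000 --save-interval 1000 \
       --seed 2 -o traj.xyz
cgslab analyze-density --traj traj.xyz --equil 0.5 -o profile.tsv
```

Output of the last two steps (`seq-stats` first):

```
id                   length  q  charged_percent  positive  negative ...
polyampholyte_b1_s0  30      0  100.0            0.5000    0.5000
```

```json
{
  "polyampholyte_b1_s0": {
    "C_sat_mgml": 1.5e-17,
    "dense_mgml": 616.7,
    "phase_separated": true,
    "width": 6.7,
    "z0": 16.7
  }
}
```

Reading: the 15 lysines and 15 glutamates (net charge 0, 100% charged)
condense into a slab of ≈617 mg/mL density with an interface of width
≈7 Å centered ≈17 Å from the slab midplane; at this short desk-scale run
essentially no chains populate the dilute phase, so the measured C_sat is
zero to numerical precision. The strictly alternating isomer
(`--blockiness 0.0`) stays dispersed under the same protocol -- the
charge-patterning dependence that distinguishes strong from weak
polyampholyte phase separators.

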