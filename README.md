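# glycanmc

Coarse-grained Monte Carlo modelling of unbranched homopolysaccharide
chains (cellulose-, amylose- and curdlan-like glucans) driven by 2D
glycosidic free-energy maps.

Polysaccharide chain conformation is dominated by the two torsions of each
glycosidic linkage, φ and ψ. Enhanced-sampling molecular dynamics produces
2D free-energy maps F(φ, ψ) for a single linkage, but extrapolating from a
single-linkage map to the shape of a chain of hundreds of residues is out
of reach for atomistic simulation. `glycanmc` bridges that gap with two
Metropolis Monte Carlo models that take such maps (or conformer energy
ladders read off them) as their only physical input:

* **1D discrete-state model** (`glycanmc.mc1d`) — the chain is a list of
  linkages, each in one of a few conformer states (*exo-syn*, *anti*-φ,
  *anti*-ψ) with fixed relative energies. Its headline observable is the
  run-length statistic **L**: the average uninterrupted length of
  ground-state fragments, L = (ground-state linkages)/(number of runs),
  a rigidity scale expressed in linkages.
* **Coarse-grained 3D model** (`glycanmc.cgmc`) — three backbone atoms per
  residue (the repeating −C_n–C_1–O− motif) with fixed bond lengths,
  angles and ring dihedral; the per-linkage backbone torsions (Φ, Ψ) are
  sampled from the free-energy map by Metropolis moves, with a 0.4 nm
  hard-sphere excluded volume between non-neighboring atoms.

A polymer-statistics layer (`glycanmc.polystats`) turns sampled ensembles
into end-to-end distances, radii of gyration, bond autocorrelations C(n),
and the persistence length l_p by three routes: inverting the Kratky–Porod
worm-like-chain relation

    ⟨e2e²⟩ = 2 l_p l_c − 2 l_p² (1 − exp(−l_c/l_p)),

inverting the Benoit–Doty relation

    ⟨R_g²⟩ = l_c l_p/3 − l_p² + 2 l_p³/l_c − (2 l_p⁴/l_c²)(1 − exp(−l_c/l_p)),

and fitting C(n) = exp(−n b / l_p), with b the mean residue-to-residue
(O-to-O) bond length and l_c = b × n_bonds the contour length.

`glycanmc.fem` reads, validates, shifts and interrogates free-energy maps
(the 3-column text dialect of metadynamics post-processing tools), finds
and classifies their minima, and `glycanmc.synthetic` generates
Gaussian-basin maps, packaged conformer energy tables and discrete
worm-like-chain ensembles with analytically known l_p, so the whole stack
is testable without any MD data.

## Worked example

Run the 1D model for a three-state linkage (relative conformer energies
0, 11.5 and 7.4 kJ/mol, a cellulose-like β(1→4) ladder) on a
2000-linkage chain at 298 K:

```sh
$ glycanmc mc1d --energies 0,11.5,7.4 --n-linkages 2000 --n-sweeps 20200 --seed 1
mean L = 17.64 +/- 0.043 (analytic 17.64, 2010 samples, acceptance 0.066)
```

The sampled mean run length (17.6 linkages) coincides with the analytic
infinite-chain value 1/(1 − p₀) where p₀ is the ground state's Boltzmann
weight: stretches of ~18 consecutive linkages share the lowest-energy
conformation before a kink interrupts them.

Sample a 60-residue chain from a synthetic single-well (Φ, Ψ) map and
estimate its persistence length three ways:

```sh
$ glycanmc make-fem --basin 180,180,20,18 --grid-step 4 --plateau 20 --out well.dat
$ printf 'ring_dihedral: 180.0\n' > geom.yaml
$ glycanmc cgmc --fem well.dat --geometry geom.yaml --n-residues 60 \
      --n-sweeps 8200 --seed 5 --traj-out traj.xyz
400 samples; <e2e> = 17.1 nm, <Rg> = 6.01 nm, acceptance 0.094 (9057 clash rejections)
$ glycanmc polystat traj.xyz
e2e_nm        17.0976   0.261
Rg_nm         6.00999   0.105
b_nm          0.479766
lc_nm         28.3062
lp_e2e-WLC_nm 7.48115   0.33
lp_Rg-WLC_nm  7.3139    0.512
lp_acf-fit_nm 7.94167   0.139
```

The three estimators agree (l_p ≈ 7.3–7.9 nm): a chain whose contour
length (28.3 nm) is a few persistence lengths is semiflexible, consistent
with its mean end-to-end distance (17.1 nm) falling well short of full
extension. The second column is a block-average uncertainty.

The same machinery is available as a library:

```python
import glycanmc as g

model = g.StateModel([0.0, 11.5, 7.4], temperature=298.0)
res = g.run_1d_mc(model, n_linkages=2000, n_sweeps=20200, seed=1)
print(res.mean_L(), g.analytic_L(model))   # 17.64 17.64
```

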