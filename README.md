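# slend

Simplest-level electron nuclear dynamics (SLEND) for proton- and
electron-induced reactions on small biomolecular prototypes.

Proton radiation deposits most of its energy in a narrow Bragg peak,
where 80–100 keV protons collide predominantly with cell water and,
directly or through radiolysis products, damage DNA.  Modeling these
events needs a method that treats scattering, fragmentation and
electron transfer *at once*, without precomputed potential energy
surfaces and without the Born–Oppenheimer assumption.  `slend` is such
a simulator for desk-scale prototypes: H⁺ + water clusters (radiolysis
and electron-transfer cross sections), H⁺ + small targets, and electron
attachment at chosen virtual orbitals (the post-capture stage of
dissociative electron attachment, e.g. at phosphate sites — the
single-strand-break pathway).

## The model

The nuclei are classical (the zero-width limit of frozen Gaussian wave
packets); the electrons are one complex spin-unrestricted determinant
in the Thouless parametrization over a UHF reference,

    χ_h = φ_h + Σ_p z_ph φ_p ,   1 ≤ h ≤ N_e ,

with basis functions travelling on the nuclei (optionally carrying the
electron-translation plane-wave phase e^{i v·r}).  The time-dependent
variational principle turns the trial state into a coupled Pfaffian
system over y = (Re z, Im z, R, P),

    Ω(y) ẏ = ∂E_total/∂y ,   Ω = K + J ,
    K_ij = −2 Im ∂² ln S / ∂X'_i ∂X''_j ,

where S is the Thouless-state overlap and J the canonical nuclear
symplectic block — classical nuclei variationally coupled to the
electrons through the non-adiabatic coupling blocks C, C_X, C_XY.
Everything downstream of a trajectory (fragment channels, Mulliken
charge series, transfer probabilities P(b), integral cross sections
σ = 2π∫P(b) b db, the cluster scaling law σ(n) = c·n^(2/3)) lives in
the analysis layer.  See `docs/methods.md` for the full account.

## Worked example

A 1 keV proton on H₂ at impact parameter 1 Bohr (the shipped demo
config):

```sh
$ slend run examples/h2_1kev.yaml --out runs/demo
manifest: runs/demo/manifest.json

$ slend analyze runs/demo/b001.000_o000.h5
frames: 165, t_end = 374.90 a.u.
fragments: ['H2', 'H']
channel: H + H2
fragment charges: [0.0234 0.9766]
```

The trajectory runs until the projectile passes the 45-Bohr separation
threshold (375 a.u. ≈ 9.1 fs).  The hydrogen molecule survives the
passage; the departing projectile fragment carries Mulliken charge
+0.977, i.e. it picked up 0.023 electrons — the recorded one-electron
transfer probability for this (b, orientation) point is
`P = 0.0234` in `manifest.json`.  Total energy is conserved to ~1e-9
Hartree and the summed Mulliken charge stays +1 to machine precision
along the run.

A single-point SCF of the water monomer in the polarization basis:

```sh
$ slend scf h2o --basis 6-31g*
E(UHF) = -76.0105299766 Hartree (11 iterations, K=19)
  O   q = -0.8663
  H   q = +0.4332
  H   q = +0.4332
```

Sweeping `b_list`/`orientations` in a config produces manifests that
`slend xsec` reduces to P(b) curves, cross sections and — when several
cluster sizes are present — the σ(n) = c·n^(2/3) fit with its R².  The
full-scale 100 keV / 6-31G* water campaign configuration is shipped as
`examples/h2o_100kev_xsec.yaml` (hours on one CPU).  Electron
attachment runs use `scenario.kind: attachment` and `slend attach-run`;
nucleotide geometries enter as user XYZ paths wherever a fixture name
is accepted.

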