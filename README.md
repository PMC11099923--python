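# nmrdock

Solution-NMR experiments can map a protein–protein interface without ever
crystallising the complex: chemical-shift perturbations (CSP) locate the
binding surfaces, paramagnetic relaxation enhancement (PRE) from a
nitroxide spin label yields long-range distance restraints, and
saturation-transfer difference (STD) experiments pin short-range contacts
to a single saturated proton.  `nmrdock` turns those three sparse, noisy
observables into a scored rigid-body model of the complex, the way
membrane-receptor/adaptor complexes (for example, a receptor's
intracellular helices binding a PDZ domain) are modelled in practice.

The package is aimed at structural-biology groups who want a small,
fully-inspectable, deterministic pipeline — every stage is a plain Python
function over peak lists and PDB files, and a built-in synthetic-data
generator with exact ground truth makes every stage testable end to end
with no downloads.

## The models

**CSP mapping.**  For each backbone amide the combined ¹H/¹⁵N perturbation
is

    Δδ_HN = sqrt( Δδ_H² + (Δδ_N / 5)² )

and residues are called *active* (candidate interface) by an iterative
trimmed threshold: values above μ + 3σ are excluded until the statistics
stabilise, and the cutoff is μ + σ of the remainder.

**PRE distances.**  A spin label raises the transverse relaxation of a
proton at distance r by the Solomon–Bloembergen rate

    Γ₂(r) = (K / r⁶) · (4 τc + 3 τc / (1 + ω_H² τc²))

and the observed paramagnetic/diamagnetic intensity ratio is modelled as

    I/I₀ = R₂,dia / (R₂,dia + Γ₂) · exp(−Γ₂ t_evol)

which is strictly increasing in r and inverted numerically to produce
distance restraints (upper bounds below the detection window, lower bounds
above it, target ± 4 Å inside it).  Labels on several cysteines give one
ambiguous restraint with minimum-distance semantics.

**STD proximity.**  Residues whose fractional attenuation
1 − I_on/I_off clears a threshold (and a spectrum-wide noise floor) get an
upper-bound restraint of 6 Å to the saturated source proton.

**Restraint-guided docking.**  CSP-active residues become ambiguous
interaction restraints (AIRs, r⁻⁶ effective distance to the partner's
active+passive surface).  A simplified rigid-body engine samples uniform
orientations, places the ligand around the receptor's restraint-active
face, minimises a composite score (AIR + PRE + STD violation energies +
soft-sphere clash) over the six rigid-body degrees of freedom with ten
restart trials per pose, then Z-scores, clusters and ranks the ensemble.

## Worked example

Run the full synthetic pipeline (generate a toy complex, simulate all three
experiments, derive restraints, dock, analyse contacts):

```
$ nmrdock run --seed 7 --outdir out7
top pose: score 0.183, Z -1.280, cluster size 13
report: out7/report.json
```

The top pose violates no AIR or STD restraint (E_air = E_std = 0), has no
steric overlap, and carries a residual PRE violation energy of 0.183 — a
Z-score of −1.28 against the 200-pose ensemble, in a 13-member cluster.
The report also records the restraint counts by source
(`{'CSP': 25, 'PRE': 75, 'STD': 1}`: 25 ambiguous interface restraints,
one PRE restraint per receptor amide, one STD contact), the interface
residues and salt bridges of the top pose, and — because the synthetic
ground truth is known — the top pose's interface-ligand RMSD to the true
complex: 2.06 Å for this seed, i.e. the docked model reproduces the true
binding mode.

Individual stages are also exposed:

```
$ nmrdock simulate --seed 7 --outdir sim7
$ nmrdock csp sim7/csp_free_A.list sim7/csp_bound_A.list -o csp.csv
cutoff 0.0370 ppm; active [3, 5, 6, 7, 9, 10, 13, 14, 17, 18, 20, 25]
$ nmrdock std sim7/std_off.list sim7/std_on.list -o std.csv
flagged [21]
```

The printed CSP cutoff is the trimmed μ + σ threshold in ppm; residues
above it define the active surface.  The flagged STD residue is the
receptor amide closest to the saturated ligand proton.

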