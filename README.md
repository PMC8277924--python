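# hydrashell

Global-optimization search and hydration-shell analysis for hydrated
calcium-ion clusters Ca²⁺(H₂O)_n.

How many water molecules directly coordinate a Ca²⁺ ion, and how do the
outer hydration shells organise as a cluster grows? These questions sit
under a lot of solution biochemistry (calcium signalling, channel
selectivity) and are usually attacked by globally searching the cluster
potential-energy surface for each composition, then analysing the
lowest-energy structures. `hydrashell` packages that workflow for
structural modellers:

* a **Lamarckian genetic algorithm** with cut-and-splice crossover that
  searches Ca²⁺(H₂O)_n geometries and returns a deduplicated,
  energy-ranked pool of local minima;
* an analytic **ion–water potential** (SPC-like flexible water +
  ion–O Lennard-Jones, calibrated to the observed first-shell Ca–O
  distance) with energy, analytic gradient, and a fast hybrid
  L-BFGS/Newton minimizer — plus a documented backend contract so a
  quantum-chemistry engine can substitute;
* **shell & hydrogen-bond analysis**: geometric H-bond detection,
  shell assignment (first shell by ion–O distance, outer shells by
  H-bond graph distance), populations N₁/N₂/N₃, bond count N_HB and
  mean Ca–O / O–O distances;
* **energetics**: counterpoise BSSE bookkeeping
  ΔE_BSSE = Σᵢ [Eᵢ^full − Eᵢ^frag], sequential water binding energy
  ΔE_seq = E(H₂O) + E[Ca²⁺(H₂O)_{n−1}] − E[Ca²⁺(H₂O)_n], per-ligand
  interaction energy E_I/N₁ = (E[cluster] − E(Ca²⁺) − E[(H₂O)_n])/N₁,
  and harmonic (RRHO) ZPE / 298 K corrections for 0 K-vs-finite-T
  isomer ranking;
* **synthetic fixtures** with planted shell labels and H-bond topology,
  so every analysis stage is testable without external data, and a
  brute-force multistart oracle that independently validates the GA.

See `docs/methods.md` for the models, numerical choices and
limitations.

## Worked example

```python
import hydrashell as hs

model = hs.REFERENCE_MODEL
pool = hs.evolve(10, model, hs.GAConfig(rng_seed=7))
best = pool.best
print(f"best energy: {best.energy:.3f} kJ/mol (found in generation {best.generation})")

hb = hs.detect_hbonds(best.geometry)
shells = hs.assign_shells(best.geometry, hb)
report = hs.shell_distances(best.geometry, shells, hb)
print(f"shells N1/N2/N3: {shells.n1}/{shells.n2}/{shells.n3}   H-bonds: {hb.n_hb}")
print(f"mean Ca-O (shell 1): {report.mean_CaO_shell1:.3f} A")
print(f"mean O-O over H-bonded pairs: {report.mean_OO_hbonded:.3f} A")

thermo = hs.harmonic_thermo(best.geometry, model, T=298.15)
print(f"ZPE: {thermo.zpe:.2f} kJ/mol   G(298 K) corr: {thermo.thermal_correction_G:.2f} kJ/mol")
```

prints

```
best energy: -1347.951 kJ/mol (found in generation 0)
shells N1/N2/N3: 7/3/0   H-bonds: 6
mean Ca-O (shell 1): 2.493 A
mean O-O over H-bonded pairs: 2.755 A
ZPE: 827.97 kJ/mol   G(298 K) corr: 671.99 kJ/mol
```

Reading this: the 10-water global minimum of the reference potential
puts seven waters in direct contact with the ion (mean Ca–O 2.49 Å,
inside the experimentally reported 2.38–2.52 Å window) and three in a
second shell, each hydrogen-bonded to the first shell (O–O 2.75 Å);
none of the first-shell waters hydrogen-bond each other. The ZPE and
Gibbs corrections are what the 0 K vs 298 K isomer ranking uses.

The same stages are available from the shell:

```bash
hydrashell search  --formula Ca:10 --seed 7 --out pool/
hydrashell analyze pool/*.xyz --out table.csv
hydrashell thermo  pool/n10_rank00.xyz -T 298.15
hydrashell run     --sizes 10-18 --seed 1 --out bundle/
```

`run` emits the full report bundle: per-size pool structures
(extended XYZ with energies in the comment line), the shell/distance
table, the energetics table (E_min, ZPE, thermal corrections, ΔE_seq,
E_I/N₁) and the 0 K / 298 K candidate ranking, all with fixed
formatting — identical config and seed reproduce the bundle
byte-for-byte.

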