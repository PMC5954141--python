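# chemibody

Analytics for structure-guided design of small-molecule–antibody
conjugates ("chemibodies"): hybrids in which an antibody binds a surface
epitope of a target while a covalently linked small molecule occupies a
deep pocket of the same protein — the motivating system is a
dipeptidyl-peptidase-IV (DPP-IV) inhibitor tethered through a PEG linker
to an engineered cysteine on an inhibitory antibody Fab.

The package covers the three computational stages of such a design
campaign, plus the synthetic data needed to exercise them end to end:

1. **Conjugation-site selection** (`chemibody.sites`): rank antibody
   residues by four structural criteria — high solvent exposure
   (Shrake–Rupley SASA relative to Gly-X-Gly reference areas), minimal
   antigen contact (heavy-atom pairs within 4.5 Å), short Cβ-to-ligand
   distance, and a Cα→Cβ vector oriented toward the ligand pocket.
2. **Linker evaluation** (`chemibody.linker`, `chemibody.confsearch`):
   build the piperazine–PEG(n)–thioether conjugate as a molecular graph
   and run a stochastic torsion search over the MMFF94 surface with the
   warhead head group and the cysteine Sγ *fixed* at their bound
   positions. Two metrics per linker length *n*:

   * strain energy `E_min(constrained) − E_min(unconstrained)`
     (kcal/mol) — a linker too short to bridge the ~28 Å gap pays a
     large penalty;
   * the number of distinct constrained conformers within 2.0 kcal/mol
     of the constrained minimum (RMSD deduplication at 0.25 Å) — an
     entropic proxy for how floppy the bound linker is.
3. **Assay analytics** (`chemibody.assay`): percent-of-control
   normalization, four-parameter-logistic IC50 fits
   (`POC = bottom + (top − bottom)/(1 + (x/IC50)^h)`, Levenberg–
   Marquardt with multi-start), Michaelis–Menten fits, fold-potency
   ratios, and the Pearson correlation between calculated linker strain
   and measured potency.

## Worked example

```python
import chemibody as cb

# mass bookkeeping for the published warhead amide analog
from rdkit import Chem
m = cb.molecular_mass(Chem.MolFromSmiles(cb.COMPOUND_SMILES["amide-analog"]))
print(f"{m.formula}  [M+H]+ = {m.mh_plus:.2f}")
# C17H23F3N4O2  [M+H]+ = 373.18

# strain of a 3-PEG vs 6-PEG linker bridging 28 Å
anchors = cb.make_anchor_pair(28.0, seed=0)
for n in (3, 6):
    g = cb.build_conjugate_linker(n)
    r = cb.strain_energy(g, anchors, cb.SearchParams(seed=0, max_iterations=120))
    print(f"n={n}: strain {r.strain:.1f} kcal/mol, {r.n_low_energy} low-energy conformers")
# n=3: strain 407.7 kcal/mol, 7 low-energy conformers
# n=6: strain 18.6 kcal/mol, 8 low-energy conformers

# recover a potency from simulated triplicate dose-response data
d = cb.simulate_dose_response(0.56, cv=0.05, replicates=3, seed=42)
fit = cb.fit_four_pl(d)
print(f"IC50 = {fit.ic50:.3f} nM (truth 0.56)")
# IC50 = 0.572 nM (truth 0.56)
```

The 3-PEG linker cannot span 28 Å (its maximum extension is ~22 Å), so
holding it in the bound pose costs hundreds of kcal/mol, while 6 PEG
units bridge the gap almost for free — which is why mid-length linkers
are optimal for this design.

The same stages run from the shell:

```bash
chemibody simulate complex --seed 0 --out toy.pdb
chemibody sites --structure toy.pdb --antibody L --antigen A \
    --ligand LIG --attachment C1 --out sites.csv
chemibody linkerscan --n 3:8 --separation 28 --seed 0 --out scan.csv
chemibody run --out results/   # full pipeline, one global seed
```

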