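# cmap2struct

Reconstruction of protein structures — single chains and cyclic
homomultimers such as tetrameric ion channels — from **ternary
residue–residue contact maps**, with structural and pore-electrostatics
model assessment.

A contact map is a symmetric L×L matrix over {1, 0, −1}: 1 for a residue
pair within a distance threshold (default Cα–Cα ≤ 8 Å), 0 for a known
non-contact, −1 for *unknown* (imposes nothing).  Given such a map the
package answers two questions that matter to anyone working with
predicted contacts:

1. **How do you get a full-atom model out of a contact map?**
   Stochastic trace reconstruction (seeded random initialization +
   iterative restraint projection), chirality resolution, ideal-geometry
   backbone completion, template-based side-chain placement with greedy
   clash relief, and — for channels — dummy-loop handling of chain
   concatenation plus C₄ symmetry projection (each reconstruction yields
   order + 1 candidate channels, one per subunit plus one from the
   averaged subunit).

2. **How much (and what kind of) contact knowledge do you need?**
   An experiment runner degrades the map — positive-only (all 0 → −1),
   randomly reduced (known entries → −1), erroneous (entries flipped) —
   reconstructs seeded model ensembles, and scores them: global/subset/
   per-residue RMSD (mirror-aware and chain-permutation-aware, since maps
   encode neither handedness nor chain labels), channel diameter, contact
   density CD = (1/L)Σcᵢ, and the electrostatic potential profile along
   the pore axis from a finite-difference two-dielectric Poisson solve
   (ε = 4 protein / 80 electrolyte), parameterized by Fmax, Fmin, zmin
   and RMSE against a template profile.

Everything runs on built-in synthetic systems (ideal helix, β-hairpin,
compact coil, a C4 toy channel with a charged pore ring); real PDB files
plug in through the same interfaces.

## Worked example

```python
import numpy as np
from cmap2struct import fixtures, derive_cmap, contact_density, ReconConfig, pipeline, evalmetrics

# a C4 toy channel: 4 x 14 residues around a 5 A pore
native = fixtures.make_toy_tetramer(14, pore_radius=5.0)
cmap = derive_cmap(native, threshold=8.0, atom_mode="CA")
print(f"L={cmap.L}  CD={contact_density(cmap):.2f}")

channels = pipeline.run_multimer_pipeline(
    cmap, native.sequence(), ReconConfig(seed=2), loop_length=6
)
rmsds = [evalmetrics.global_rmsd(c, native, permute_chains=True)[0] for c in channels]
diam = evalmetrics.structure_diameter(channels[int(np.argmin(rmsds))],
                                      native.metadata["marker_seq_index"], ("A", "C"))
print(f"best of {len(channels)} channels: RMSD {min(rmsds):.2f} A, diameter {diam:.2f} A"
      f" (native {2 * native.metadata['pore_radius']:.1f} A)")
```

prints

```
L=56  CD=7.71
best of 5 channels: RMSD 3.11 A, diameter 12.15 A (native 10.0 A)
```

i.e. from the complete map of this 56-residue channel the pipeline
recovers the assembly to ≈ 3 Å heavy-atom RMSD with the pore diameter
within ≈ 2 Å of the construction value.  With a `positive_only` map the
same pipeline collapses the channel (diameter shrinks far below native
and RMSD roughly doubles) — non-contact knowledge is what holds a
structure open.

The same machinery is scriptable from the shell:

```sh
c2s fixtures make --kind toy_tetramer --n 14 --out native.pdb
c2s cmap derive native.pdb native.cmap --threshold 8.0
c2s pipeline --cmap native.cmap --multimer --seed 2 --out-dir models/
c2s evaluate --model models/channel_0.pdb --native native.pdb --diameter-residue 10
```

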