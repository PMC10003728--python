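# vhhdyn

Conformational-dynamics analysis of nanobody (VHH) ensembles with the
Protein Blocks structural alphabet.

Single-domain camelid antibodies (VHHs, nanobodies) bind antigen through
three hypervariable loops (CDR1–3) mounted on a conserved framework
(FR1–4).  Their engineering depends on understanding which regions are
*rigid*, which are *flexible* (local backbone conformational change), and
which are merely *mobile* (a rigid fragment displaced as a whole) or
*deformable* (local change without net displacement).  Cα fluctuation
alone cannot separate those behaviours; combining it with a structural
alphabet can.

`vhhdyn` takes conformational ensembles (multi-model PDB, e.g. simulation
snapshots) together with a multiple sequence alignment of the domains and
computes, per residue and per alignment column:

* **Protein Block assignment** — each residue's 8-dihedral window
  (ψ<sub>i−2</sub>, φ<sub>i−1</sub>, ψ<sub>i−1</sub>, φ<sub>i</sub>,
  ψ<sub>i</sub>, φ<sub>i+1</sub>, ψ<sub>i+1</sub>, φ<sub>i+2</sub>) is
  assigned to the nearest of 16 reference prototypes *a*–*p* under the
  RMSDA dissimilarity (root mean square of wrapped angular differences).
* **Neq** — the effective number of blocks sampled at a position,
  `Neq = exp(−Σₓ fₓ ln fₓ)` over the block frequencies `fₓ`
  (1 = one conformation, 16 = uniform over the alphabet), with
  ΔNeq = |Neq¹ − Neq²|.
* **ΔPB / ΔAA** — the L1 distance `Σₓ |f¹ₓ − f²ₓ|` ∈ [0, 2] between two
  block (or amino-acid) frequency vectors at one column.
* **RMSF** — Cα root mean square fluctuation about the ensemble mean
  after iterative Kabsch superposition, plus per-domain z-score
  normalisation `(vᵢ − μ)/σ` of RMSF and experimental B-factors.
* **MSA-guided clustering** — domains are compared by
  `d(v, w) = 1/(n−m) Σᵢ |vᵢ − wᵢ|` over the columns where both domains
  have a residue, then grouped by complete-linkage hierarchical
  clustering (alternative distance: column-averaged ΔPB); two
  clusterings are compared via a contingency table and the adjusted Rand
  index.
* **Flexibility quadrants** — each position is classified by thresholding
  normalised RMSF (default 2.0) against Neq (default 3.0):
  flexible (> 2, > 3), mobile (> 2, ≤ 3), deformable (≤ 2, > 3),
  rigid otherwise.

Because real microsecond trajectories are bulky and rarely shareable, the
package ships a synthetic-ensemble generator (`vhhdyn.synthetic`) that
produces multi-class families of domains with gapped alignments and exact
ground truth for every stage: known generating blocks, known RMSF closed
forms, known class partitions and known target quadrants.

## Worked example

```python
from vhhdyn import default_family_spec, gen_family, cluster_by_rmsf, classify_domains
from sklearn.metrics import adjusted_rand_score

spec = default_family_spec(n_classes=4, domains_per_class=5,
                           n_frames=200, seed=42)
fam = gen_family(spec)                       # 20 domains, 120-column MSA

res = cluster_by_rmsf(fam.ensembles, fam.msa, k=4)
truth = [fam.class_labels[d] for d in res.domain_ids]
print(adjusted_rand_score(truth, res.labels))

table = classify_domains(fam.ensembles, fam.msa)
print(table["label"].value_counts().to_dict())
row = table[(table.domain_id == "c0_d0") & (table.column == 24)].iloc[0]
print(f"column 24: rmsf_norm={row.rmsf_norm:.2f} neq={row.neq:.2f} -> {row.label}")
```

prints

```
1.0
{'rigid': 1957, 'flexible': 140, 'mobile': 128, '': 80, 'deformable': 40}
column 24: rmsf_norm=2.66 neq=4.97 -> flexible
```

The ARI of 1.0 means the complete-linkage clustering of MSA-projected
RMSF profiles recovered the four generating dynamics classes exactly.
Column 24 sits in the core of a loop generated in the flexible regime:
its z-scored RMSF (2.66) and effective block count (4.97) both exceed
their thresholds, so the residue is labelled flexible.  The empty label
counts the chain-end positions ('Z', no complete 5-residue window).

The same flow is available from the shell:

```sh
vhhdyn simulate --preset family --seed 42 --out-dir sim
for p in sim/*.pdb; do vhhdyn metrics "$p" --out "$(basename $p .pdb).tsv"; done
vhhdyn cluster c*_d*.tsv --msa sim/family.fasta --k 4 --out-prefix clusters
```

`clusters.labels.tsv` then lists one cluster per generating class with no
singletons.  The remaining subcommands are `assign` (PB matrices and
per-position frequencies), `project` (per-column aggregation with FR/CDR
annotation), `classify` (quadrants) and `termini` (CDR end-to-end CA
distances).  Region intervals, thresholds and clustering parameters come
from a YAML `--config`; two interval presets (`main`, `alt`) cover the
published variants of the CDR boundaries in MSA coordinates.

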