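# ppiscreen

Structure- and ligand-based triage for small molecules that block a
protein–protein interaction. The package grew out of the search for
inhibitors of the JUNO–IZUMO1 egg–sperm recognition complex, and it covers
the computational backbone of that kind of campaign end to end:

1. **Hot spots** — frozen virtual alanine scanning of the receptor's
   interface residues. Each residue's side chain is truncated beyond the
   C-beta with all coordinates frozen; the binding-affinity loss
   (*delta affinity*, kcal/mol) is the summed pairwise attraction between
   the deleted atoms and the partner, and residues losing ≥ 4 kcal/mol are
   hot spots.
2. **Pose profiling** — geometric hydrogen bonds, attractive van der Waals
   contacts (heavy-atom pairs with d/(r_i + r_j) in [0.89, 1.30]), and
   buried surface area (two-sided Shrake–Rupley, probe 1.4 Å).
3. **Criteria and ranking** — required hot-spot interaction sets (full
   site and two sub-sites), Best/Worst labeling by thresholds on docking
   score, VDW contacts, and BSA, and a rank-sum ordering over the three
   properties.
4. **ISE screening** — an Iterative Stochastic Elimination filter
   ensemble: conjunctions of descriptor-range clauses are sampled
   stochastically, scored by training Matthews correlation coefficient
   (MCC), and the (descriptor, bin) values over-represented among bad
   candidates are iteratively eliminated. A molecule's index is
   (n_pass − n_fail)/n_filters ∈ [−1, 1]; an enrichment curve of TP/FP per
   index threshold selects the screening cutoff.
5. **Synthetic data** — generators for toy complexes with planted
   geometry, pose tables, and learning sets with planted class shifts, each
   with a machine-readable truth ledger, so the whole pipeline is testable
   without any external downloads.

Docking scores are always *ingested* — this package never docks.

Intended users: computational chemists who have docking output and complex
structures in hand and want an open, deterministic, tested implementation
of the triage and classification layer.

## Worked example

Label and rank the ten reference pose records that ship with the package
(docking score in kcal/mol, attractive VDW contact count, BSA in Å²):

```python
import ppiscreen as pp

print(pp.filter_and_count(list(pp.REFERENCE_POSES)))
for i, r in enumerate(pp.rank_molecules(list(pp.REFERENCE_POSES))[:3], 1):
    print(f"{i}. {r.molecule_id}  score={r.docking_score}  "
          f"vdw={r.vdw_contacts}  bsa={r.bsa}")
```

```
{'Best': 4, 'Worst': 0, 'neither': 6}
1. Z56788505  score=-5.4  vdw=316  bsa=1039.0
2. Z49734016  score=-7.0  vdw=453  bsa=779.0
3. Z49720304  score=-4.0  vdw=292  bsa=843.0
```

Four of the ten records fall in the Best region (score < −3, BSA ≥ 750,
≥ 250 contacts), none in the Worst region, and the rank-sum over the three
properties puts Z56788505 first (ranks 2 + 2 + 1).

Train and evaluate the ISE classifier on a synthetic learning set
(68 Best / 69 Worst molecules, 50 descriptors of which 3 carry a 2-SD
shift):

```python
table, informative = pp.make_learning_set(pp.LearningSetSpec(seed=17))
result = pp.cross_validate(table, k=5, seed=17)
curve = pp.enrichment_curve(result.scores["index"], result.scores["label"])
cutoff = pp.select_cutoff(curve, min_ratio=3.0)
```

```
informative descriptors: ['D005', 'D035', 'D041']
filters in final model: 22
top filter MCC: 0.767
TP/FP at index -1: 0.986
selected cutoff: -0.333 (TP/FP 3.16)
```

At the lowest threshold every molecule is selected, so TP/FP is the class
ratio 68/69 ≈ 0.99; raising the index cutoff trades recall for precision,
and the smallest threshold reaching three-fold enrichment becomes the
screening cutoff.

The same flow runs from the command line:

```sh
ppiscreen simulate learning-set --seed 17 --out sim/
ppiscreen train-ise --table sim/learning_set.csv --seed 17 --out model.json
ppiscreen screen --model model.json --table sim/learning_set.csv --cutoff 0.5
ppiscreen hotspots --pdb complex.pdb --receptor A --partner B --threshold 4.0
ppiscreen run --config pipeline.yaml   # full pipeline with manifest
```

## Layout

```
src/ppiscreen/
  structures.py   # PDB parsing, interface residues, alanine scan, hot spots
  pose.py         # H-bonds, VDW contacts, SASA/BSA
  criteria.py     # interaction criteria, Best/Worst labels, ranking
  descriptors.py  # RDKit 2D descriptor table + manifest + pruning
  ise.py          # ISE training, index scoring, CV, enrichment, cutoff
  synthetic.py    # toy complexes, pose tables, learning sets (+ truth)
  pipeline.py     # YAML-config orchestration with run manifest
  cli.py          # `ppiscreen` command-line interface
docs/methods.md   # model assumptions, parameter rationale, limitations
```
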