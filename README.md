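# pessp

Phylogeny-based enzymatic substrate specificity prediction (PESSP) for
nitrilases, plus the enzyme-characterization arithmetic used to verify the
predictions at the bench.

## The problem

Sequence databases are full of proteins annotated only as "nitrilase" or
"unnamed protein product". Annotation transfer by top-BLAST-hit routinely
gets the *reaction* right but the *substrate* wrong: two nitrilases at 66%
identity can both hydrolyze mandelonitrile while a 90%-identity pair
prefers different substrates entirely. PESSP predicts substrate specificity
from phylogeny instead: curate a mined candidate set, build a bootstrapped
neighbor-joining tree, find the clade that contains **every** enzyme whose
specificity is experimentally defined, and predict that specificity for the
clade's uncharacterized members. This package implements that pipeline as a
tested library (`src/pessp/`), a CLI (`pessp`), and a set of analysis
drivers (`analysis/`), with a synthetic-data generator standing in for
database mining and wet-lab assays so every stage is verifiable offline.

It is aimed at enzyme-discovery and molecular-evolution practitioners who
want a reproducible, scriptable version of the classic
mine → curate → align → NJ + bootstrap → clade-designation workflow.

## Methods at a glance

- **Curation.** Identity window (keep 30% ≤ id ≤ 90% to the query), at most
  two uncharacterized hits per identity value, per-organism sequence dedup
  (distinct loci from one strain are kept), and an ordered Glu-Lys-Cys
  catalytic-triad scan for hits annotated "unnamed protein product".
  Experimentally defined references always survive. Every removal is audited.
- **Alignment & distances.** Affine-gap global alignment (BLOSUM62, gap
  open 10 / extend 0.5) with deterministic traceback; guide-tree progressive
  MSA (UPGMA on 1 − identity/100); p-distance with pairwise gap deletion
  (Poisson correction `d = −ln(1−p)` optional).
- **Trees.** Saitou–Nei neighbor joining with the Q-criterion
  `Q(i,j) = (k−2)d(i,j) − r_i − r_j`, lexicographic tie-breaks, negative
  branch estimates clamped with deficit transfer; column-resampled bootstrap
  (default n = 1000); extended majority-rule consensus with per-split
  support percentages.
- **Prediction.** The subgroup is the smallest bipartition side spanning all
  defined references; its uncharacterized members are emitted as candidates,
  ranked by identity to the query, suppressed when clade support < 50%.
- **Characterization.** Michaelis–Menten fitting via the Lineweaver–Burk
  double-reciprocal regression (`Vmax = 1/intercept`, `Km = slope/intercept`,
  nonlinear refit available as a cross-check), specificity constant
  `kcat/Km`, specific activity (U/mg), relative-activity profiles with an
  N.D. detection floor, enantiomeric excess `100·|R−S|/(R+S)`, and
  native/subunit oligomer stoichiometry.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Rediscover a planted subgroup end to end (also available as
`analysis/02_simulate_family.py` + `analysis/03_run_pessp.py`):

```python
from pessp import SimulationConfig, simulate_family, run_pipeline
from pessp.records import CurationConfig

cfg = SimulationConfig(seed=7)   # 39 taxa, 12-member subgroup, 5 labeled
fam = simulate_family(cfg)
report = run_pipeline(
    fam.records, fam.sequences,
    target_function=cfg.target_function,
    bootstrap_n=200, seed=7,
    curation_cfg=CurationConfig.passthrough(),
)
print(report.candidates.to_string(index=False))
```

prints

```
 accession          predicted_label  clade_support  identity_pct  rank
SYN_000011 mandelonitrile hydrolase          100.0          93.7     1
SYN_000008 mandelonitrile hydrolase          100.0          85.7     2
SYN_000007 mandelonitrile hydrolase          100.0          76.3     3
SYN_000004 mandelonitrile hydrolase          100.0          75.7     4
SYN_000001 mandelonitrile hydrolase          100.0          69.7     5
SYN_000005 mandelonitrile hydrolase          100.0          66.0     6
SYN_000009 mandelonitrile hydrolase          100.0          58.3     7
```

— the designated clade has 12 members at 100% bootstrap support, and the 7
predicted candidates are exactly the planted uncharacterized subgroup
members (precision = recall = 1.0). The same run from the shell:

```sh
pessp simulate --seed 7 --outdir fam/
pessp run --config run.yaml --outdir out/     # table/fasta/target in run.yaml
```

On the characterization side, fitting noiseless initial-rate data generated
at Km = 0.14 mM, Vmax = 45.4 µmol·min⁻¹·mg⁻¹ over 0.1–15 mM
(`analysis/04_characterize_enzyme.py`):

```
noiseless Lineweaver-Burk: Km 0.1400 mM, Vmax 45.40 umol/min/mg (r^2 1.000000)
kcat/Km = 1.1e+05 M^-1 s^-1
native/subunit MW ratio 12.16 -> 12 subunits
mandelonitrile/phenylacetonitrile activity ratio 8.8 (7 substrates below detection)
product enantiomeric excess 98.4% (R)
optimum temperature 45 C (profile normalized to max)
```

The Km/Vmax are recovered exactly (the double-reciprocal transform is exact
without noise); the specificity constant 1.1×10⁵ M⁻¹s⁻¹ comes from the
measured turnover number 15.4 s⁻¹; the 12-subunit count follows from the
450 kDa native vs 37 kDa subunit masses; the 8.8× activity ratio marks the
enzyme as a mandelonitrile-preferring arylacetonitrilase.

## Analysis drivers

| script | what it does |
| --- | --- |
| `analysis/01_curate_reference_set.py` | re-screens the packaged 39-entry candidate table and audits what the identity rules remove |
| `analysis/02_simulate_family.py` | generates the synthetic study family (39/12/5) with ground truth |
| `analysis/03_run_pessp.py` | full pipeline on the synthetic family; precision/recall vs the planted truth |
| `analysis/04_characterize_enzyme.py` | kinetic fits, specificity constant, oligomer state, activity profiles, ee |

All outputs are written under `results/` (regenerated on each run).

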