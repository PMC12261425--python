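# falafl

Fair multi-sample selection of CpG sites from low-coverage single-cell
methylation sequencing data, by integer linear programming.

## The problem

Single-cell bisulfite sequencing covers each cell's genome extremely
sparsely, and the coverage differs strongly between cells and between
patients. When a cohort study needs one common panel of CpG sites, the
obvious choice — keep the sites covered in the most patients — is biased:
it over-represents the deeply sequenced patients and starves the rest.

`falafl` selects the *largest* weighted site set that is explicitly fair
to every patient. With `s̄_ij = 1` when site `j` has sufficient coverage
in patient `i` (after a three-step preprocessing: δ-filter on covered-cell
fractions, binarization at `p`, minimum-patient-count filter `k`), it
solves

```
maximize   Σ_j r_j Σ_i s̄_ij
subject to Σ_j r_j s̄_ij  ≥  q · Σ_j r_j     for every patient i
```

over binary indicators `r_j`: each patient must have good coverage in at
least a fraction `q` (default 0.75) of the selected sites. The decision
version is NP-hard (reduction from Exact Cover by 3-Sets, included), but
after merging identical matrix columns the HiGHS solver handles
cohort-scale inputs in seconds.

Around the optimizer the package provides the full companion analysis:
Jensen–Shannon lineage-informativeness of sites on a per-patient cell
tree, the deviation-from-perfect-correlation universality metric and the
universally-(un)informative classification, CpG island/shore/shelf/
inter-CGI annotation, three naive selection baselines with
shuffle-robustness and balance reports, and seeded synthetic-data
generators for all of it. See `docs/methods.md` for the science and the
numerical choices.

## Worked example

```python
import numpy as np
from falafl import select, shuffle_robustness

# 2 patients x 3 sites; site 1 covered in both, sites 2-3 in one each
S = np.array([[1, 1, 0],
              [1, 0, 1]])

res = select(S, q=0.5)
print(res.selected, res.objective, res.per_patient_fraction)
# [0 1 2] 4 [0.66666667 0.66666667]

res = select(S, q=0.75)
print(res.selected, res.objective, res.per_patient_fraction)
# [0] 2 [1. 1.]
```

At `q = 0.5` every site can be kept: each patient covers 2 of the 3
selected sites (fraction 0.67 ≥ 0.5), and the objective — the total
number of (patient, site) coverage events over the selection — is 4.
Tightening to `q = 0.75` forces the selection down to the one site both
patients share; each patient now covers 100 % of the panel.

The same model as a scikit-learn selector:

```python
from falafl import FalaflSelector
sel = FalaflSelector(q=0.75).fit(S)
sel.transform(S)          # -> the selected columns, shape (2, 1)
sel.per_patient_fraction_ # -> array([1., 1.])
```

And from the shell, end to end:

```bash
falafl preprocess --input fractions.tsv --delta 0.1 --p 0.5 --out binary.tsv
falafl select --input binary.tsv --q 0.75 --out selected.bed --report report.tsv
falafl bench --method shuffle --input binary.tsv --q 0.75 --out jaccard.tsv
```

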