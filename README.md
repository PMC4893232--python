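# bloodmeal

Analysis of mosquito blood-meal surveys: who bites whom, and what that
implies for pathogen transmission.

Field surveys of engorged ("blood-fed") mosquitoes identify the vertebrate
host of each specimen from gut-content DNA. `bloodmeal` turns such a table
of records — mosquito taxon, host species, site, date, trap method, land
use — into the standard host-feeding-pattern analysis used in medical
entomology:

* **Summary tables** of mosquito taxa and host species, with hosts
  collapsed into three groups (birds, non-human mammals, humans) through an
  explicit taxonomy, and host-range breadth (the share of mosquito species
  that fed on each host).
* **Seasonal, land-use and trap comparisons** — chi-square tests of
  host-group composition between the early (Jan–Jun) and late (Jul–Dec)
  sampling period, Kruskal-Wallis tests across land-use classes, and
  pairwise trap-method tests with multiple-comparison adjustment.
* **C-score null models** of host co-occurrence. For a binary host × column
  matrix the C-score is the mean number of checkerboard units over row
  pairs, C = mean_{i<j} (r_i − S_ij)(r_j − S_ij); significance comes from
  fixed-equiprobable randomization (row totals preserved, columns
  equiprobable), classifying the pattern as *aggregated* (hosts shared),
  *segregated* (hosts mutually exclusive) or *random*.
* **Feeding-group clustering** — Jaccard dissimilarity on binary
  bird/mammal/human profiles under UPGMA; zero-height clusters are the
  feeding groups (taxa with identical host-group combinations).
* **Transmission-risk indices** per taxon: risk(birds→humans) = Ap·Fa·Fh
  and risk(mammals→humans) = Ap·Fm·Fh, where Ap is relative abundance and
  Fa/Fh/Fm the avian/human/mammalian blood-meal fractions.
* **In-silico host identification** — IUPAC-aware search for the published
  cytochrome-*b* primer pairs (L2513/H2714, ~244 bp; fallback
  L14841/H15149, ~358 bp), amplicon extraction, and two-tier best-identity
  assignment against a reference panel.
* **Synthetic data** — a survey generator with known ground truth (host
  choice = preference ⊙ availability ⊙ trap bias), co-occurrence scenario
  matrices (aggregated/segregated/random) and mutated amplicon sets, so
  every stage is testable end to end.

The package ships the aggregate tables of a nationwide German survey (775
blood-fed specimens, 2012–2015, 20 named species plus four aggregate taxa,
32 host species) and a deterministic record-level reconstruction consistent
with every published count.

## Worked example

```python
from bloodmeal import NullModelConfig, build_matrix, run_null_model, tables

survey = tables.reconstruct_survey()
matrix = build_matrix(survey)             # rows: host species, cols: mosquito taxa
result = run_null_model(matrix, NullModelConfig(seed=1, n_iterations=5000))
print(result.summary_line("survey (host x mosquito taxa)"))
```

prints

```
survey (host x mosquito taxa)	C-score 1.476	Mean ± Variance 4.250 ± 0.038	P<exp 0.0002	P>exp 1	Aggregated
```

The observed C-score (1.476) sits far below the randomization mean (4.250):
host species co-occur on the same mosquito taxa much more than chance —
an *aggregated* feeding pattern, i.e. most mosquito species share common
hosts (90 % of the named species fed on humans, 65 % on roe deer). The
seasonal comparison for the dominant taxa (`examples/seasonal_and_trap_tests.py`)
prints

```
Aedes vexans                           chi2=  5.80002 df=2 P=0.0550
Culex pipiens pipiens form pipiens     chi2=  0.40438 df=2 P=0.8169
Ochlerotatus cantans                   chi2=  0.00340 df=1 P=0.9535
```

— no significant early/late shift in host-group composition. Each script in
`examples/` demonstrates one capability (summaries, null models, clustering,
risk ranking, host identification, synthetic surveys) and ends with a note
on how to read the numbers.

A thin CLI wraps the same library:

```sh
bloodmeal summarize --out-dir out/
bloodmeal nullmodel --seed 1 --out-dir out/
bloodmeal cluster --out-dir out/
```

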