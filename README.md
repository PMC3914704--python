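# karyoclust

Chromosome-level structural variation analysis for tumor cell lines, starting
from the text every cytogenetics lab actually produces: ISCN karyotype
strings.

Established breast-cancer cell lines such as MCF7, T47D, BT474 and SKBR3 are
not cytogenetically uniform. When 19–26 metaphases of a line are karyotyped
by G-banding and M-FISH, the result is a *composite karyotype* — one ISCN
string like

```
76~88<4n>,-X[11],-Xx2[8],+7[26],der(6)t(6;17;16)(q25;q21;?)[26],...[cp26]
```

in which each aberration carries a bracketed count of the metaphases bearing
it (`[11]` of `[cp26]`), a multiplicity suffix for repeated losses/gains
(`-Xx2` = both X copies lost… twice over the `<4n>` baseline), and nothing
about which metaphase carries what. `karyoclust` turns such strings into
structured data and reproduces the two standard analyses built on them:

- **Within a line** — how heterogeneous are the metaphases? Each aberration
  entry is scored present/absent per metaphase (for composite input, a
  seeded frequency-constrained reconstruction), and metaphases are clustered
  with Euclidean distance and Ward's minimum-variance linkage.
- **Across lines** — which aberrations are shared, at what frequency? Every
  event is collapsed to an identity (numerical: *(direction, chromosome)*;
  structural: the canonical event text, multiplicity stripped), the identity ×
  line matrix of metaphase fractions is assembled, and both aberrations and
  lines are Ward-clustered.

Ward's method is implemented via the Lance–Williams recurrence with
deterministic lexicographic tie-breaking, in both the minimum-variance
convention ("ward", as in `hclust(..., "ward.D2")`/scipy) and the legacy
unsquared one ("ward.D"). A `WardClustering` estimator (scikit-learn
`fit`/`fit_predict` API) wraps the same machinery.

A synthetic generator (`karyoclust.simulate`) draws per-metaphase karyotypes
with a known clonal core, optional subclones at set fractions, sporadic
Poisson noise and per-identity multiplicity distributions, so every pipeline
stage can be validated against planted ground truth.

The composite karyotypes of the four lines above, as published, ship as the
bundled fixture `src/karyoclust/data/table1_karyotypes.txt`; the lenient
parsing mode loads them verbatim, repairing (and reporting) the notational
irregularities of the printed table.

## Worked example

```sh
$ karyoclust stats src/karyoclust/data/table1_karyotypes.txt --outdir out
MCF7: 31 numerical, 28 structural
T47D: 25 numerical, 26 structural
BT474: 35 numerical, 35 structural
SKBR3: 29 numerical, 33 structural
```

MCF7 carries 31 distinct numerical identities (e.g. `-18`, `-18x2`, `-18x3`
and `-18x4` all collapse to *loss of 18*) and 28 distinct structural ones.
`out/summary.json` adds, per line, the clonal set (identities in every
metaphase — for MCF7 that includes `+7`, `+17` and
`der(6)t(6;17;16)(q25;q21;?)`) and nullisomy percentages: under MCF7's
near-tetraploid baseline, `-20x4[8]` means chromosome 20 is completely absent
in 8/26 = 30.8% of metaphases, and `-18x4[3]` gives 11.5% for chromosome 18.

```sh
$ karyoclust across src/karyoclust/data/table1_karyotypes.txt --k 5 --outdir out
156 identities x 4 lines; 4 shared at >= 0.5
```

The cross-line frequency table holds 156 identities; four numerical losses
(`-4`, `-15`, `-18`, `-X`) are carried by ≥ 50% of metaphases in *every*
line. `out/lines.nwk` contains the cell-line dendrogram:

```
(MCF7:2.80953484,((T47D:2.429975082,BT474:2.429975082):0.0910082579,SKBR3:2.52098334):0.2885515001);
```

T47D and BT474 pair first, SKBR3 joins them, and MCF7 — with its large
private block of high-frequency structural aberrations — is the outlier, the
last line to join. `out/aberration_clusters.tsv` cuts the aberration
dendrogram at k = 5: one cluster collects the numerical changes common to all
four lines, the other four are line-specific.

```sh
$ karyoclust within src/karyoclust/data/table1_karyotypes.txt --seed 1 --outdir out
MCF7: 26 metaphases x 100 entries (reconstruction, seed 1)
...
```

writes, per line, the reconstructed binary metaphase × entry matrix, metaphase
and aberration dendrograms (Newick), and flat cluster labels. Reconstruction
is stochastic but seeded: reruns with the same seed are byte-identical.

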