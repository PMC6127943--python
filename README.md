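# kgscreen

Drug efficacy screening from a protein-level knowledge graph, using the
predicate and provenance information that similarity- and distance-based
methods throw away.

## The problem

A biomedical knowledge graph stores subject-predicate-object triples
between proteins ("OPRM1 — forms protein complex with — GNAT2"), each
attested by one or more provenance sources (Reactome, CTD, literature
extraction, ...). Representing a drug by its set of target proteins (DT)
and a disease by its set of associated proteins (DP), the screening
question is binary classification: is this drug-disease combination
efficacious?

`kgscreen` extracts the paths of length ≤ 2 connecting DT to DP in three
scenarios — *overlap* (a protein in both sets, possibly with a
self-relationship), *direct* (one triple joins a DT and a DP), and
*indirect* (DT–IP–DP through one intermediate protein, the two steps
DTIP and IPDP kept separate) — and encodes each combination as a binary
feature vector: for each path slot (SELF, DIRECT, DTIP, IPDP), one bit
per predicate label and one per provenance source, set iff some triple of
that slot carries that label, plus three bare co-occurrence flags. For a
vocabulary of 45 predicates and 25 sources the full space has
1 + 4 × (45 + 25) = 281 features. Random forests classify the
combinations under repeated balanced 10-fold cross-validation (fresh
random negative sample each repeat; ROC AUC / PR AUC over out-of-fold
scores). Feature-set variants (`baseline`, `predicate`, `provenance`,
`full`, `indirect_only`) isolate what each information type contributes,
and a network-proximity baseline — the mean closest hop distance
d_c(T,S) = mean_t min_s d(t,s), z-scored against a degree-matched random
null — provides the benchmark that uses no predicate or provenance
information.

Because production knowledge graphs of this kind are commercial, the
package includes a synthetic generator (`kgscreen.synthgen`) that
emulates their statistical shape and plants controllable predicate /
provenance signal, with path structure matched between classes so that
co-occurrence alone is uninformative. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
from kgscreen import CVConfig, SynthConfig, combos_to_xy, generate, run_repeated_cv

bundle = generate(SynthConfig(n_proteins=300, n_pos=60, n_neg=120, seed=7))
cv = CVConfig(n_repeats=5, n_folds=5, n_trees=100, seed=3)
for variant in ("baseline", "provenance", "predicate", "full", "indirect_only"):
    X, y, spec = combos_to_xy(bundle.graph, bundle.combos, variant)
    res = run_repeated_cv(X, y, cv, feature_names=spec.names)
    print(f"{variant:13s} {len(spec):3d} features  "
          f"AUC {res.mean_auc:.1f}% ({res.sd_auc:.1f}%)")
```

prints

```
baseline        3 features  AUC 46.5% (3.2%)
provenance    101 features  AUC 71.7% (4.5%)
predicate     181 features  AUC 91.4% (3.3%)
full          281 features  AUC 90.0% (3.9%)
indirect_only 140 features  AUC 76.5% (7.4%)
```

The three co-occurrence flags alone sit at chance (the generator matches
path structure between classes by design), provenance bits recover part
of the planted signal, predicate bits — planted stronger — recover more,
and the full set performs on par with the best single type. The
indirect-only variant shows the method still works when overlap and
direct-relationship evidence is discarded. `run_repeated_cv` also returns
normalized feature importances; on this benchmark the top-ranked columns
are the planted signal labels (e.g. `DIRECT:predicate:P43`).

The same experiments are available from a shell via the `kgscreen` CLI
(`simulate`, `cv`, `ablate`, `proximity`, `stratify`, `paths`); all
inputs and outputs are plain TSV/JSON — see `kgscreen --help`.

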