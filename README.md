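# narragraph

Speech-graph analysis of narrative transcripts. The pipeline turns
plain-text narratives into directed word multigraphs, computes fifteen
graph attributes on fixed-length moving token windows (verbosity
control), and correlates the windowed attribute means with ADHD
symptom-checklist scores using Spearman and covariate-controlled partial
Spearman correlations with Bonferroni-corrected thresholds. A synthetic
cohort generator with tunable repetition/back-reference mechanics
provides ground truth for every stage.

## Layout

| module | role |
|---|---|
| `narragraph.text_processing` | tokenization, stop-word removal (bundled pt/en lists) |
| `narragraph.graph_core` | word multigraph construction + 15 attributes (N, E, WC, RE, PE, L1–L3, LCC, LSC, ATD, D, DI, ASP, CC) |
| `narragraph.windowed_analysis` | moving windows (default 30 tokens, 50% overlap) and per-narrative attribute means |
| `narragraph.scales` | ASRS scoring: items rated ≥ 2 count as positive symptoms, 9/9 domain split |
| `narragraph.stats` | Spearman / partial Spearman (Pearson on rank residuals), Bonferroni thresholds, attribute × scale correlation tables |
| `narragraph.synthetic_data` | seeded narrative and cohort generators with symptom-linked recurrence mechanics |

## CLI

```bash
# generate a synthetic cohort (transcripts/ + subjects.csv)
narragraph simulate --n 60 --seed 7 --outdir sim/

# windowed attribute means, one row per subject
narragraph attributes --transcripts sim/transcripts --out profiles.csv \
    --window 30 --overlap 0.5

# correlation table (plain Spearman; add --covariates for partial)
narragraph correlate --profiles profiles.csv --metadata sim/subjects.csv \
    --covariates age,iq,education_years,bdi,stai_state,stai_trait,upps_total \
    --out table.csv
```

`attributes` uses the bundled Portuguese stop-word list by default
(`--language en` or `--stopwords FILE` to override). The correlation
table has rows TNW, RE, L1, LSC, ASP by three symptom scales (total,
inattention, hyperactivity-impulsivity); the four graph attributes are
flagged at the Bonferroni-corrected threshold (0.05/4 = 0.0125), TNW at
the nominal 0.05.

## Conventions worth knowing

- E, RE, L1 and ATD count edge *occurrences* (multiplicity); density D
  uses distinct directed non-self edges so it stays in [0, 1].
- RE defaults to excess traversals (m − 1 per repeated pair);
  `re_mode="total"` counts every occurrence of a repeated pair.
- DI/ASP/CC are computed on the undirected simple projection within the
  largest weak component; `distance_mode="directed"` switches DI/ASP to
  directed distances within the largest strongly connected component.
- Single-node graphs yield D = DI = ASP = CC = 0 by convention.
- TNW defaults to the cleaned (post-stop-word) token count;
  `tnw_source="raw"` switches to the pre-removal count.
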