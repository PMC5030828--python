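# toxclust

Chemical category formation for read-across from repeated-dose toxicity
data.

Regulatory frameworks (REACH, the Cosmetics Directive) push hazard
assessment away from animal testing and toward **read-across**: predicting
a chemical's toxicity from tested structural analogs. That requires
*categories* — groups of chemicals that are similar both structurally and
toxicologically. `toxclust` builds such categories from repeated-dose
study records (organ-effect findings with LOELs, the lowest observed
effect levels) and chemical structures, for toxicologists and
cheminformaticians who need reproducible, data-driven category proposals.

## What it does

1. **Ingest & curation** (`chemdata`): reads compounds (SMILES/SDF) and a
   study CSV (one organ-effect finding per row); keeps reliable rat
   studies by oral/inhalation route, subacute (28–32 d) or subchronic
   (84–99 d), purity ≥ 90%; maps organ-effect pairs onto aggregated
   endpoints through a user glossary; keeps the lowest LOEL per
   (compound, endpoint, duration class) and converts mg/kg → mmol/kg
   bw/day with the molecular weight; drops endpoints observed for < 5% of
   compounds.
2. **Features** (`features`): binary substructure bits from named SMARTS
   lists (a MACCS-key-like list plus two bundled functional-group lists)
   together with molecular weight and logP.
3. **Potency discretization** (`potency`): per endpoint, a deterministic
   1-D two-means clustering on log₁₀ dose finds a high/low threshold,
   clamped into 1.5–2.0 mmol/kg bw/day for subacute studies; subchronic
   LOELs are compared to half the threshold. A compound with LOEL ≤ t is
   **high-potency**.
4. **Imputation** (`imputation`): an Ensemble of Classifier Chains fills
   the (typically ~82%) missing potency cells so the tree sees a complete
   target matrix. Imputed cells stay flagged and are excluded from every
   downstream statistic.
5. **Clustering** (`pct`): a **Predictive Clustering Tree** over the
   structural features with the multi-endpoint potency matrix as target.
   At each node, the split test maximizing the target-variance reduction

   &nbsp;&nbsp;ΔVar = Var(S) − Σₖ (nₖ/n)·Var(Sₖ),&nbsp;
   Var(S) = (1/n) Σᵢ ‖yᵢ − ȳ‖²

   is chosen, accepted only if an F-test (F = Var(S)/pooled child
   variance, df (n−1, n−2)) is significant at α = 0.125; leaves hold
   ≥ 3 compounds; no pruning, no ensembling. Leaves are the clusters, each
   carrying a majority-vote toxicity profile used to predict untested
   compounds.
6. **Assessment** (`clusterstats`): per-compound *toxic value* (Σ of
   grades: missing 0, low 1, high 2), cluster LOEL summaries (geometric
   mean, range, gm/min ratio), quantitative read-across candidates
   (gm/min ≤ 5, with an additional assessment factor of 5 advised),
   category grades 1/2/3 from structural/toxicological similarity, 2×2
   chi-square feature enrichment with Holm correction, and Spearman
   endpoint correlations — all on observed (non-imputed) data.
7. **Synthetic data** (`synthdata`): a seeded generator emulating the
   statistical shape of the (confidential) real datasets — latent
   scaffold-linked clusters, ~82% missing cells, ~49% high-potency among
   observed — so the full pipeline is testable end to end.

## Worked example

```bash
python examples/03_readacross_summaries.py
```

```
glycol/alcohol cluster (24 members): LOEL gm 2.79 mmol/kg, range 0.06-137.88, gm/min ratio 46
-> ratio far above 5: qualitative grouping only

published candidate clusters, re-ranked by recomputed gm/min ratio:
  cluster  61: gm 0.52 mmol/kg, ratio 1.1
  cluster  13: gm 0.58 mmol/kg, ratio 1.8
  ...
```

The 24-member glycol/alcohol cluster is toxicologically coherent (shared
alcohol-dehydrogenase metabolism; kidney/liver/RBC/spleen targets) but its
LOELs span four orders of magnitude, so only clusters with a tight range
(gm/min ≤ 5) are proposed for *quantitative* read-across: for those, the
cluster geometric-mean LOEL divided by an additional factor of 5 can stand
in for a missing point of departure.

Other examples: `01_build_categories.py` (full pipeline on synthetic
data), `02_potency_discretization.py` (threshold detection),
`04_enrichment.py` (which structural features track spleen toxicity:
nitrogen motifs p ≈ 5·10⁻⁶, ethers p ≈ 8·10⁻⁵), and
`05_assign_new_compound.py` (routing novel analogs down the tree). A thin
CLI wraps the same functions: `toxclust simulate | build | assign |
summarize | enrich | export-tree`.

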