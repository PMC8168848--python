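# taxroi

Tools for prioritizing taxonomic research for conservation with a
return-on-investment (ROI) analysis of structured expert-elicitation
data.

Many recognized species — especially in diverse groups such as
Australian squamate reptiles — hide undescribed "candidate" species that
are invisible to conservation assessment until they are formally named.
Expert panels can triage this backlog: for each species they record how
confident they are that taxonomic revision is needed, whether revision
would increase or decrease species counts (or hit an intractable
"species complex"), which research steps remain before a revision can be
completed, and whether the resulting candidate species would matter for
conservation. `taxroi` turns such assessment tables into a reproducible
pipeline: validation and multi-assessor conflict resolution, per-species
ROI scores, headline summary statistics, and gridded richness /
mean-score maps from species range polygons. A calibrated synthetic-data
generator emulates a continent-scale elicitation so every stage is
testable without any external data.

## The ROI statistic

For each species judged *highly probable* or *definite* to need revision
with a predicted **increase** in species number:

```
ROI = (c1 + c2 + c3 + c4) × tax / (r1 + r2 + r3 + r4)
```

* `c1..c4` — binary conservation benefits: description enables formal
  assessment; a candidate species is highly localized (extent of
  occurrence < 20,000 km², the Red List Vulnerable range threshold); a
  species-level threatening process applies; high probability of a
  VU/EN/CR listing.
* `r1..r4` — binary outstanding research costs: fieldwork/sampling,
  genetics/genomics, morphology/phenotype, analysis & manuscript.
* `tax` — confidence weight that revision is needed: 0 (no revision),
  0.2 (probably not), 0.8 (highly probable), 1.0 (definite).

Species with `ROI ≥ 1` (configurable threshold) are priorities: high
predicted conservation payoff relative to the research still required.
For mapping, per-cell layers on an equal-area grid (default 25 km cells,
EPSG:3577) give species richness and the weighted mean score — the sum
of scores of species present divided by the number present — optionally
square-root transformed to damp a few extreme cells.

## Worked example

```python
from taxroi import synthetic, assessment_io, summaries, roi

config = synthetic.SyntheticConfig(seed=1)          # 1,034-species pool
records, labels = synthetic.generate_assessments(config)
resolved, conflicts = assessment_io.resolve_conflicts(records, labels)

cen = summaries.census(resolved, n_total_species=config.n_species)
print(f"assessed {cen.n_assessed}/{cen.n_total_species} "
      f"({summaries.round_half_up(cen.pct_assessed)}%), "
      f"revision needed {cen.n_revision} "
      f"({summaries.round_half_up(cen.pct_revision_of_assessed)}%)")

cohort = assessment_io.roi_cohort(resolved)         # increases only
scores, n_priority = roi.score_cohort(cohort)
print(f"increase cohort {len(cohort)}; priority (ROI >= 1): {n_priority}")
top = scores[0]
print(f"top species {top.species_id}: ROI = {top.roi:.2f} "
      f"(benefit {top.benefit_sum}, cost {top.cost_sum}, tax {top.tax_weight})")
```

prints

```
assessed 876/1034 (84.7%), revision needed 292 (33.3%)
increase cohort 222; priority (ROI >= 1): 23
top species sp0634: ROI = 3.00 (benefit 3, cost 1, tax 1.0)
```

876 of 1,034 species could be assessed; 292 of those probably or
definitely need revision, 222 of which would add species. 23 of the 222
clear the priority threshold; the top species scores 3.0 because three
conservation benefits are predicted, the panel is certain revision is
needed (`tax = 1.0`), and only analysis/manuscript work remains
(`cost = 1`).

The gridding worked example (`synthetic.make_worked_example_fixture`)
places six species with ROI scores (1, 1, 1, 1, 3, 4) in one 25 km cell:
that cell's richness is 6, its weighted mean 11/6 ≈ 1.83, and its
square-root-transformed mean ≈ 1.354.

A command-line interface mirrors the library: `taxroi validate`,
`taxroi score`, `taxroi summarize`, `taxroi grid`, and `taxroi simulate`
(see `taxroi <cmd> --help`).

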