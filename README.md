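# cogmarker

Lexicon-based detection and prevalence analysis of cognitive-distortion
markers in Dutch chat transcripts.

The package ships a 12-category lexicon of Dutch cognitive-distortion
schemata (short word patterns written in a small regex dialect), matches
them against role-tagged chat messages, and computes the statistics used to
compare cohorts:

- **`cogmarker.lexicon`** — the packaged verbatim lexicon, its parser
  (comma-space row splitting, typographic-quote cleanup), and the pattern
  compiler (case-insensitive, Unicode-NFC, whitespace-collapsed matching
  with word-boundary anchoring and an optional-gap construct).
- **`cogmarker.corpus`** — data model and I/O for chat sessions (JSONL and
  long-format CSV), per-individual timelines, and plain-text sentence
  corpora; system-message exclusion.
- **`cogmarker.matcher`** — the per-message presence indicator per category,
  with matched pattern ids retained for diagnostics.
- **`cogmarker.prevalence`** — pooled cohort prevalence, within-session
  prevalence distributions, monthly prevalence series, and prevalence
  ratios between roles.
- **`cogmarker.cohorts`** — Bartlett variance test, Welch t test, pooled-SD
  Cohen's d, Bonferroni adjustment, and all-pairs cohort comparison tables.
- **`cogmarker.synthetic`** — seeded synthetic chat corpora with known
  role/category injection probabilities, built from a filler vocabulary
  verified to never trigger the lexicon, plus a pattern realizer (samples a
  concrete string accepted by each pattern) and ground-truth labels for
  exact parameter-recovery checks.
- **`cogmarker.cli`** — the `cogmarker` command.

## CLI

```sh
# generate a seeded synthetic corpus with known injection rates
cogmarker simulate --config sim.json --outdir sim/

# annotate a corpus (JSONL, CSV, or sentence mode) with category indicators
cogmarker score --corpus sim/corpus.jsonl --outdir scored/

# prevalence for one role: pooled, per session, or per month
cogmarker prevalence --annotations scored/annotations.csv \
    --corpus sim/corpus.jsonl --role h --by month --outdir prev/

# Bartlett / Welch / Cohen's d comparison of labelled cohorts
cogmarker compare "seekers=scored/annotations.csv:h" \
    "counselors=scored/annotations.csv:o" --outdir cmp/

# end-to-end per-category prevalence + ratios ranked by magnitude
cogmarker report --corpus sim/corpus.jsonl --with-comparison --outdir rep/
```

A `sim.json` simulation config looks like:

```json
{
  "n_sessions": 1000,
  "seed": 1,
  "mean_messages": {"h": 15, "o": 12},
  "injection": {"h": {"dr": 0.10, "p": 0.06, "ss": 0.06},
                "o": {"dr": 0.07, "ss": 0.04, "m": 0.03}},
  "start_month": "2019-01",
  "n_months": 12
}
```

Category codes: `c` catastrophizing, `dr` dichotomous reasoning, `dtp`
disqualifying the positive, `er` emotional reasoning, `f` fortune-telling,
`lam` labeling and mislabeling, `mam` magnification and minimization,
`mf` mental filtering, `m` mindreading, `o` overgeneralizing,
`p` personalizing, `ss` should statements. Roles: `h` help seeker,
`o` counselor, `b` system (excluded from analysis).

Every command writes a `manifest.json` with its full configuration, so runs
are reproducible from the manifest alone.

## Notes on the packaged lexicon

The lexicon resource is a verbatim copy of its printed source table. Seven
of the twelve category rows split cleanly to the documented per-category
counts; for the remaining five the printed row text and the documented
count disagree (stray typographic quotes, likely typesetting loss), and
this package treats the printed rows as canonical — 253 patterns in total.
Raw pattern text is preserved byte-for-byte; normalization and the
compiled form are derived from it.
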