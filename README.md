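# pvscreen

Case/non-case disproportionality screening for spontaneous-report
pharmacovigilance databases. The package models a MedDRA-style term hierarchy
(SOC > HLGT > HLT > PT), a three-table individual-case-safety-report (ICSR)
store, rule-based case selection with a reproducible audit trail,
reporting-odds-ratio (ROR) screening with log-scale Wald confidence
intervals and signal-of-disproportionate-reporting (SDR) flagging, and
descriptive cohort summaries (characteristics, time-to-onset). Because real
pharmacovigilance databases are access-restricted, it ships a synthetic ICSR
generator whose injected drug–event associations have an exact closed-form
population ROR, so the whole pipeline is testable end to end against known
ground truth.

## Layout

| module | purpose |
|---|---|
| `pvscreen.meddra` | term hierarchy, dictionary file I/O, renal HLT scope |
| `pvscreen.fixtures` | bundled example dictionary and drug list |
| `pvscreen.icsr` | ICSR data model, three-table CSV dialect (see `DIALECT.md`) |
| `pvscreen.synth` | synthetic database generator, analytic expected ROR, duplicate injection |
| `pvscreen.selection` | deduplication, inclusion/exclusion rules, selection audit |
| `pvscreen.disprop` | 2×2 tables, ROR + 95% CI, SDR flag, grid screening |
| `pvscreen.summaries` | characteristics table, time-to-onset summaries |
| `pvscreen.forest` | forest-plot data export (+ optional SVG) |
| `pvscreen.cli` | `pvscreen` command-line pipeline |

## CLI

```sh
# full pipeline on the bundled demo model (synthetic data, 1 injected signal)
pvscreen all --out results/demo --seed 1

# or with an explicit config
pvscreen all --config config.yaml --out results/run1
pvscreen simulate --config config.yaml --out data/     # store + dictionary files
pvscreen screen --config config.yaml --out results/ --min-cases 5 --z 1.96
pvscreen screen --config config.yaml --out results/ --no-dedup   # ablation
```

Example `config.yaml`:

```yaml
seed: 1
synthetic:
  n_reports: 20000
  drug_marginals: {imatinib: 0.2, dasatinib: 0.2, nilotinib: 0.2, bosutinib: 0.2, ponatinib: 0.2}
  pt_marginals: {PT_RF: 0.02, PT_NS: 0.02, PT_AKI: 0.02}
  signals:
    - {drug_code: nilotinib, pt_code: PT_NS, odds_multiplier: 6.0}
  duplicate_rate: 0.02
  consumer_reporter_rate: 0.10
screen: {min_cases: 5, z_multiplier: 1.96}
```

Artifacts per run: the synthetic store tables, `selection_audit.csv`, the
case-set tables, `screening.csv`/`screening.json` (full precision),
`forest.csv` plus `forest_omitted.csv` (together covering the whole
drug × event grid), `characteristics.csv`/`.json`, `tto.csv`, and
`manifest.json` (seed, config hash, counts) for byte-for-byte reproduction.

## Method notes

* ROR = (a/c)/(b/d) on a report-level 2×2 partition of the deduplicated
  store; CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96 by default.
* A pair is estimable only with strictly more than `min_cases` (default 5)
  exposed cases and no zero cell (an opt-in 0.5 continuity correction exists
  for comparability with other tools).
* SDR: ROR > 1 and CI lower bound > 1, both strict.
* No multiple-testing adjustment — screening, not confirmatory testing.
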