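# Tabular dialect

All files are delimited UTF-8 text with a mandatory header row. Comma is the
default delimiter; tab is accepted on input (the delimiter is sniffed).
Optional values are empty cells — never literals such as `NA` or `NULL`.
Dates are ISO-8601 (`YYYY-MM-DD`); partial dates (year or year-month) are
treated as missing on input.

## Report store (three tables joined on `report_id`)

### reports
| column | type | notes |
|---|---|---|
| `report_id` | text | unique |
| `report_date` | date | mandatory |
| `country` | text | ISO-like code |
| `reporter` | enum | `physician`, `pharmacist`, `other_health_professional`, `consumer`, `unknown`; empty = `unknown` |
| `age_years` | number | optional |
| `sex` | enum | `male`, `female`, `unknown`; empty = `unknown` |

### drugs
| column | type | notes |
|---|---|---|
| `report_id` | text | must exist in reports |
| `drug_code` | text | opaque (ATC-like or INN) |
| `role` | enum | `suspected`, `interacting`, `concomitant`; mandatory |
| `start_date` | date | optional |
| `action_taken` | enum | `withdrawn`, `dose_reduced`, `continued`, `unknown`; empty = `unknown` |
| `indication` | text | optional, attached per drug entry |

### reactions
| column | type | notes |
|---|---|---|
| `report_id` | text | must exist in reports |
| `pt_code` | text | preferred-term code |
| `onset_date` | date | optional |
| `outcome` | enum | `recovered`, `recovering`, `not_recovered`, `recovered_with_sequelae`, `fatal`, `unknown`; empty = `unknown` |
| `serious_flags` | set | `\|`-separated subset of `hospitalization`, `life_threatening`, `death`, `disability`, `congenital_anomaly`, `other_medically_significant`; empty cell = not reported; literal `none` = explicitly non-serious |

Every report must have at least one drug row and one reaction row. A `fatal`
outcome requires the `death` flag somewhere in the report's reactions.

## Term dictionary (two tables)

### terms: `code,name,level`
`level` is one of `SOC`, `HLGT`, `HLT`, `PT`.

### links: `child_code,parent_code`
Links connect adjacent levels only (`PT→HLT`, `HLT→HLGT`, `HLT→SOC`,
`HLGT→SOC`). Every PT needs ≥1 HLT parent; every HLT must reach ≥1 SOC.
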