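# sholink

Deterministic record linkage of a state traffic-safety registry to Medicare
enrollment data — the workflow used to connect police-reported crash,
licensing, citation, and suspension histories with insurance claims for
older-adult driving-safety research — implemented as a reusable, testable
pipeline that runs end to end on synthetic sources with a known ground-truth
crosswalk.

Motor-vehicle crashes are a leading cause of injury for adults 65 and older,
but crash registries know almost nothing about drivers' health, and claims
data know almost nothing about crashes. Linking the two gives
epidemiologists person-level exposure, event, and care trajectories. The
real files sit under data-use agreements, so this package ships a
synthetic-data module that emulates both sources — including identifier
errors, mortality, residence moves, event streams, and monthly
fee-for-service vs. capitated coverage — and every downstream stage is
validated against the generator's ground truth.

## The linkage model

Candidate record pairs (registry individual × beneficiary) are scored in
four variable categories — **name** (first and last), **sex**, **age** (dates
of birth and death), and **residence** (state and ZIP) — each rated on the
ordered scale `None < Low < Medium < High`. For example, with last names
equal, *John vs. John* rates High, *John vs. Jon* Medium (nickname-type
variant), and *John vs. Frank* Low. A first-match-wins pattern table maps
the four qualities to an overall confidence `Weak < Fair < Strong`
(all-High ⇒ Strong; High name with Medium sex/age/residence ⇒ Fair).

Five declarative acceptance strategies decide which scored pairs become
links:

| id | rule |
|----|------|
| 1 | confidence ∈ {Strong, Fair} |
| 2 | at least 3 of 4 categories High |
| 3 | name ∈ {H, M} and age = H |
| 4 | name ∈ {H, M} and age ∈ {H, M} |
| 5 | (name ∈ {H, M} and age = H) or (name, sex, residence all High) |

Strategy 5 — the default — prioritizes the age match while rescuing pairs
whose only weakness is a stale address. Contested pairs are resolved to a
unique one-to-one crosswalk (best candidate by confidence, count of Highs,
name then age quality; deterministic tie-breaks), each accepted pair
receives an opaque person key (BID), and all sources are joined on BID into
a person-month panel feeding annual cohort reports.

## Worked example

```bash
sholink all --seed 7 --n 2000 --out out
```

prints the stage log:

```
simulate: {'persons': 2000, 'in_sho': 1847, 'in_medicare': 1833, 'in_both': 1680}
finder: {'stages': [('registry individuals (licensing or crash)', 1178),
                    ('born 1900-1954, not dead before 2007-01-01', 1111),
                    ('non-missing name, sex, birth date, state, ZIP', 1105),
                    ('survived to 65th birthday', 1105),
                    ('final individuals for linkage', 1105)], 'rejects': 0}
link: {'finder': 1105, 'beneficiaries': 1099, 'candidate_pairs': 2143}
classify: {'resolved': 995, 'dropped_in_resolution': 1148, 'accepted': 971, 'strategy': 5}
integrate: {'panel_rows': 8159, 'audit_rows': 671}
report: {'cohort_n': 406, 'year': 2019}
```

The finder stages are the eligibility cascade: 1,178 registry individuals,
of whom 1,111 were born 1900–1954 and survived past 2006, 1,105 have all six
linkage identifiers, and 1,105 survived to their 65th birthday. Of those,
995 resolved candidate links remain after one-to-many resolution and 971
are accepted under strategy 5. `out/strategy_report.csv` compares all five
rules against the 1,105-person finder cohort:

```
strategy,criteria,accepted,pct_of_final
1,"Accept Strong + Fair, reject all Weak",980,88.69
2,Accept matches with 3-4 Highs,958,86.7
3,Name (High/Medium) AND Age High,946,85.61
4,Name (High/Medium) AND Age (High/Medium),975,88.24
5,"[Name (High/Medium) AND Age High] OR 3 Highs in Name, Sex, and Residence",971,87.87
```

Note the ordering 1 > 5 > 2: the confidence-only rule is the most inclusive,
the 3-of-4-Highs rule penalizes people who moved, and strategy 5 sits
between them. `out/cohort_summary.csv` characterizes the 406 linked
individuals aged 65+ who were fee-for-service covered throughout 2019 (or
until death):

```
characteristic,count,percent
N,406,100.0
Age 65-69,80,19.7
...
Female,214,52.71
```

Each stage can also be run separately (`sholink simulate`, `finder`,
`link`, `classify`, `integrate`, `report`) against the same `--out`
directory, and every run is a pure function of the config and seed — a
repeated run is byte-identical. Library use mirrors the CLI:

```python
from sholink import RunConfig
from sholink.pipeline import run_pipeline

run_pipeline(RunConfig(seed=7, n_persons=2000, out_dir="out"))
```

## Layout

- `sholink.synth` — population, error, and event generators; source export
- `sholink.finder` — eligibility cascade producing the finder file
- `sholink.matching` — blocking and category-level comparators
- `sholink.classify` — confidence, resolution, strategies, crosswalk
- `sholink.integrate` — BID joins and the person-month panel
- `sholink.report` — annual cohort selection and characterization
- `sholink.config` / `sholink.pipeline` / `sholink.cli` — orchestration

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
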