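# sevtier

Systematic, replicable disease-severity classification for expanded carrier
screening (ECS) panels.

ECS tests hundreds of recessive diseases at once, and professional
guidelines make disease severity a key inclusion criterion — but severity
has historically been assessed by labor-intensive per-disease expert
polling. `sevtier` implements a two-stage alternative for laboratories,
panel curators, and genetic counselors:

1. **Characteristic tiers.** Clinician importance ratings (1–10) of 15
   clinical characteristics of untreated genetic disease are grouped by
   Ward minimum-variance hierarchical clustering into importance **Tiers
   1–4** (Tier 1: shortened lifespan in infancy or childhood/adolescence,
   intellectual disability; Tier 4: reduced fertility). The package ships
   the reference ratings from a survey of 192 health-care professionals
   and can re-derive tiers from any respondent-level ratings CSV.
2. **Rule-based severity classes.** Any disease, described only by the
   characteristics of its untreated course (optionally with per-
   characteristic penetrance), is classified on the ordinal scale
   Mild(1) < Moderate(2) < Severe(3) < Profound(4):

   - a characteristic counts only if ≥ 25% of affected individuals show it
     (unspecified penetrance passes); the two modifiers (availability of
     treatment, variable expressivity) and Tier 4 are always excluded;
   - **R1** Profound — more than one Tier 1 characteristic;
   - **R2** Severe — exactly one Tier 1 characteristic;
   - **R3** Severe — a Tier 2 characteristic plus at least three other
     Tier 2/3 characteristics;
   - **R4** Moderate — any remaining Tier 2/3 characteristic;
   - **R5** Mild — everything else.

   Every result carries a rule trace, so the reason a disease landed in a
   bin is always reportable — e.g. for transparent informed consent.

On the 15 packaged reference diseases the classifier reproduces the
survey-derived severity group of every disease (15/15; five Profound,
eight Severe, two Moderate, none Mild).

## Worked example

```python
from sevtier import DiseaseProfile, Trait, classify

profile = DiseaseProfile(
    disease_id="usher_1f",
    name="Usher syndrome type 1F",
    traits=(
        Trait("impaired_mobility"),
        Trait("vision"),
        Trait("hearing"),
        Trait("sensory_other"),
    ),
)
result = classify(profile)
print(result.label, result.ordinal, result.deciding_rule)
for rule in result.rule_trace:
    print(f"  {rule.rule_id} fired={rule.fired}  {rule.detail}")
```

prints

```
Severe 3 R3
  R1 fired=False  tier1=0 (Profound needs >=2)
  R2 fired=False  tier1=0 (Severe needs exactly 1)
  R3 fired=True  tier2=1, tier3=3 (Severe needs a Tier 2 item + 3 others)
```

Usher 1F has no lifespan or intellectual-disability involvement, so rules
R1/R2 fail; its one Tier 2 characteristic (impaired mobility) plus three
Tier 3 sensory characteristics satisfy R3, and the disease is Severe —
matching its clinician severity rating (mean 2.65 of 4). Contrast
alpha-1 antitrypsin deficiency (two Tier 2 + one Tier 3 traits): R3 fails
and it is Moderate.

The same pipeline is available from the shell:

```sh
sevtier reproduce --outdir out/          # full reference analysis
sevtier derive-tiers --ratings my_survey.csv --outdir tiers/
sevtier classify --profiles my_panel.csv --outdir classes/
sevtier evaluate --predicted classes/classes.csv --reference groups.csv --outdir eval/
sevtier simulate --spec generator.yaml --out ratings.csv
sevtier stability --ratings ratings.csv --k 4 --B 200 --seed 0 --out freq.csv
```

`sevtier reproduce` exits non-zero with a diff report if any derived tier,
group, or classification disagrees with the packaged reference.

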