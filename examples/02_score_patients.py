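"""Score individual patients and a whole cohort with the packaged card.

The eight-variable card awards 0-3 points per variable (total 0-18); higher
scores mean more obstruction-like office findings.
"""

import booscore as bs

card = bs.default_score_card()
print(f"card: {card.name}, variables: {', '.join(card.variables)}")
print(f"maximum composite score: {bs.max_score(card)}")

patient = dict(
    age=72, ipss_vs=1.8, qmax=8.5, voided_volume=140,
    tpv=46, tzi=0.52, ipp=1.1, puv_angle=38,
)
score = bs.compute_risk_score(patient, card)
print(f"\nexample patient risk score: {score}")
for rule in card.rules:
    pts = bs.assign_points(patient[rule.variable], rule)
    print(f"  {rule.variable:14s} {patient[rule.variable]:7.2f} -> {pts} pt")

cohort = bs.generate_cohort(bs.default_generator_config(n=355, seed=42))
scores = bs.score_cohort(cohort, card)
boo = cohort["lutd_label"].isin(bs.BOO_LABELS)
print(f"\ncohort mean score: BOO {scores[boo].mean():.1f}, non-BOO {scores[~boo].mean():.1f}")
print("A gap of several points between groups is what makes a single")
print("integer threshold a usable office-based triage rule.")
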