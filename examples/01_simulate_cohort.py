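"""Generate a synthetic hotline cohort and inspect its label structure.

Builds a case-control cohort at the published size (526 high-risk calls,
531 controls), prints the marginal label rates per group and verifies the
triage rule on every record.
"""

from crisisdetect import CohortConfig, assign_high_risk, generate_cohort

cohort = generate_cohort(CohortConfig(n_high_risk=526, n_control=531, seed=0))
df = cohort.to_frame()

print(f"{len(df)} calls ({int(df.high_risk.sum())} high-risk)")
for group, sub in df.groupby("high_risk"):
    name = "high-risk" if group else "control  "
    print(
        f"{name}: depression {sub.mood_depressed.mean():.2f}  "
        f"ideation {sub.suicidal_ideation.mean():.2f}  "
        f"plan {sub.suicide_plan.mean():.2f}  "
        f"median risk score {sub.risk_score.median():.0f}"
    )

violations = sum(
    r.high_risk != assign_high_risk(r.suicidal_ideation, r.suicide_plan, r.risk_score)
    for r in cohort.records
)
print(f"triage-rule violations: {violations}")
# Every high-risk record satisfies: ideation with a plan, or ideation
# without a plan plus a risk score >= 5. Controls sit below both branches.
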