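"""Tier-1 screening of the packaged 13-pesticide risk-quotient table.

Feeds each pesticide's printed acute and chronic risk quotients through the
level-of-concern decision rule (0.5 acute, 1.0 reproduction), preserving the
censoring of quotients built on '>' toxicity endpoints.
"""

import plra

table = plra.load_fixture("table2_rq")
flagged = []
for _, row in table.iterrows():
    acute = plra.RiskQuotient(row["acute_rq"], bool(row["acute_rq_censored"]), "acute_dose")
    chronic = plra.RiskQuotient(row["chronic_rq"], bool(row["chronic_rq_censored"]), "reproduction")
    decisions = (plra.loc_decision(acute, 0.5), plra.loc_decision(chronic, 1.0))
    if "exceeds" in decisions:
        flagged.append(row["pesticide"])
    print(f"{row['pesticide']:<20} acute {str(acute):>8} -> {decisions[0]:<13}"
          f" chronic {str(chronic):>8} -> {decisions[1]}")

print(f"\n{len(flagged)} of {len(table)} pesticides exceed a level of concern:")
print("  " + ", ".join(flagged))
# these are the compounds a tiered assessment escalates to the nest-model
# tier; 'low_risk' rows stop here, which is the efficiency the tiers exist for.
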