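# Base-case inputs of the knee-arthroplasty wait-time cost-utility model.
# Utilities are annual quality weights; disutilities are one-time QALY
# deductions; probabilities are annual unless named otherwise; costs are
# dollars. Revision tiers cover implant ages [0,10), [10,20), [20,inf) years.

u_oa: 0.6
u_oa_bridge: 0.7
u_tka: 0.9
u_rev: 0.85
dis_rev: -0.1
dis_complication: -0.20
p_early_complication: 0.01
p_rev_primary_by_tier: [0.005, 0.01, 0.02]
p_rev_revision_by_tier: [0.01, 0.02, 0.04]
p_mort30_primary: 0.007
p_mort30_revision: 0.01
wait_months: 24
c_indirect_oa_annual: 10369.0
c_bridge_annual: 2500.0
c_tka: 26865.0
c_rev: 35542.0
indirect_recovery_fraction: 0.80
bridge_utility_improvement: 0.33
discount_annual: 0.03
cohort_age_years: 60
scenario: A
max_age_years: 110
include_complications: true

# one-way sensitivity ranges
sensitivity:
  u_oa: [0.4, 0.8]
  u_oa_bridge: [0.6, 0.9]
  u_tka: [0.6, 0.9]
  u_rev: [0.6, 0.9]
  dis_rev: [-0.25, 0.0]
  dis_complication: [-0.40, 0.0]
  p_early_complication: [0.0, 0.05]
  p_rev_primary_0_9: [0.0, 0.02]
  p_rev_primary_10_19: [0.0, 0.05]
  p_rev_primary_20plus: [0.0, 0.05]
  p_rev_revision_0_9: [0.0, 0.04]
  p_rev_revision_10_19: [0.0, 0.08]
  p_rev_revision_20plus: [0.0, 0.10]
  p_mort30_primary: [0.0, 0.014]
  p_mort30_revision: [0.0, 0.02]
  wait_months: [1, 60]
  c_indirect_oa_annual: [0.0, 20000.0]
  c_bridge_annual: [0.0, 3883.0]
  c_tka: [20000.0, 30000.0]
  c_rev: [30000.0, 40000.0]
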