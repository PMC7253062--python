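# Named experiment configurations for the colony-fitness sweeps.
# Every block is a Scenario: a genotype template plus sweep grids and run
# settings.  Omitted keys fall back to the package defaults:
#   m2_values [0.99, 0.95, 0.90, 0.85, 0.80], dispersal 1..9 cells/day,
#   300x300 grid, 1e6 food units, sigma 5.0, 1 founder, 100 replicates,
#   t_max 100.  Genotype defaults: M1 0.5, m_larva 0.05, m_dauer 0.005,
#   s_hungry 0.9, c_adult 1000, c_larva 50, L1s_s 6, L2s_s 30.

demo_boom:
  description: "Demo boom: no reproductive decline, 50 progeny/day, M2 0.99, dispersal 9"
  genotype: {F1: 50, F2: 0.0, M2: 0.99, s_fed: 0.9}
  m2_values: [0.99]
  dispersal_speeds: [9]

# --- no age-related reproductive decline (F2 = 0), progeny/day varied ----
no_decline_2:
  description: "2 progeny per adult per day, no reproductive decline"
  genotype: {F1: 2, F2: 0.0}
no_decline_5:
  description: "5 progeny per adult per day, no reproductive decline"
  genotype: {F1: 5, F2: 0.0}
no_decline_8:
  description: "8 progeny per adult per day, no reproductive decline"
  genotype: {F1: 8, F2: 0.0}
no_decline_20:
  description: "20 progeny per adult per day, no reproductive decline"
  genotype: {F1: 20, F2: 0.0}
no_decline_50:
  description: "50 progeny per adult per day, no reproductive decline"
  genotype: {F1: 50, F2: 0.0}

# --- curtailed reproductive schedules (F2 from F1 / span^2.5) ------------
span10_30_progeny:
  description: "30 progeny on day 1 declining to none over a 10-day span"
  genotype: {F1: 30, F2: 0.09486832980505137}
span5_30_progeny:
  description: "30 progeny on day 1 declining to none over a 5-day span"
  genotype: {F1: 30, F2: 0.5366563145999495}
span3_30_progeny:
  description: "30 progeny on day 1 declining to none over a 3-day span"
  genotype: {F1: 30, F2: 1.9245008972987527}
day1_only_4:
  description: "4 progeny on adult day 1 only (shortest reproductive span)"
  genotype: {F1: 4, F2: 4.0}

# --- day-1-only reproduction, brood size varied --------------------------
day1_only_2:
  description: "2 progeny on day 1 only"
  genotype: {F1: 2, F2: 2.0}
day1_only_5:
  description: "5 progeny on day 1 only"
  genotype: {F1: 5, F2: 5.0}
day1_only_20:
  description: "20 progeny on day 1 only"
  genotype: {F1: 20, F2: 20.0}
day1_only_50:
  description: "50 progeny on day 1 only"
  genotype: {F1: 50, F2: 50.0}

# --- adult greed: adult consumption varied, day-1-only 4 progeny ---------
low_greed:
  description: "Adult consumption 50 units/day with 4 progeny on day 1 only"
  genotype: {F1: 4, F2: 4.0, c_adult: 50}
mid_greed:
  description: "Adult consumption 250 units/day with 4 progeny on day 1 only"
  genotype: {F1: 4, F2: 4.0, c_adult: 250}
high_greed:
  description: "Adult consumption 1000 units/day with 4 progeny on day 1 only"
  genotype: {F1: 4, F2: 4.0, c_adult: 1000}

# --- larval consumption varied, adult consumption fixed at 1000 ----------
larva_greed_25:
  description: "Larval consumption 25 units/day, day-1-only 4 progeny"
  genotype: {F1: 4, F2: 4.0, c_larva: 25}
larva_greed_500:
  description: "Larval consumption 500 units/day, day-1-only 4 progeny"
  genotype: {F1: 4, F2: 4.0, c_larva: 500}

# --- age decline in adult feeding rate -----------------------------------
precipitous_feeding_decline:
  description: "Adult feeding 100% on days 1-2, zero from day 3; day-1-only 4 progeny"
  genotype: {F1: 4, F2: 4.0, consumption_schedule: [1.0, 1.0, 0.0]}

# --- robustness variations around the day-1-only 4-progeny control -------
founders_3:
  description: "Three founding larvae at the patch centre"
  genotype: {F1: 4, F2: 4.0}
  founders: 3
founders_5:
  description: "Five founding larvae at the patch centre"
  genotype: {F1: 4, F2: 4.0}
  founders: 5
founders_7:
  description: "Seven founding larvae at the patch centre"
  genotype: {F1: 4, F2: 4.0}
  founders: 7
grid_200:
  description: "200 x 200 grid, same patch"
  genotype: {F1: 4, F2: 4.0}
  width: 200
  height: 200
grid_500:
  description: "500 x 500 grid, same patch"
  genotype: {F1: 4, F2: 4.0}
  width: 500
  height: 500
patch_x5:
  description: "Fivefold larger food patch (5e6 units)"
  genotype: {F1: 4, F2: 4.0}
  total_food: 5.0e6
patch_half:
  description: "Halved food patch (5e5 units)"
  genotype: {F1: 4, F2: 4.0}
  total_food: 5.0e5
flat_patch:
  description: "Flatter patch morphology (sigma x2) at fixed total food"
  genotype: {F1: 4, F2: 4.0}
  sigma: 10.0
steep_patch:
  description: "Steeper patch morphology (sigma / 2) at fixed total food"
  genotype: {F1: 4, F2: 4.0}
  sigma: 2.5
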