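opv0_window_days: 14
doses:
- vaccine: BCG
  dose_number: 0
  visit_number: 1
  scheduled_age_days: 0
  min_age_days: 0
  max_age_days: 1825
  min_interval_days: 0
- vaccine: OPV
  dose_number: 0
  visit_number: 1
  scheduled_age_days: 0
  min_age_days: 0
  max_age_days: 14
  min_interval_days: 0
- vaccine: OPV
  dose_number: 1
  visit_number: 2
  scheduled_age_days: 42
  min_age_days: 42
  max_age_days: 1825
  min_interval_days: 28
- vaccine: Penta
  dose_number: 1
  visit_number: 2
  scheduled_age_days: 42
  min_age_days: 42
  max_age_days: 1825
  min_interval_days: 0
- vaccine: PCV
  dose_number: 1
  visit_number: 2
  scheduled_age_days: 42
  min_age_days: 42
  max_age_days: 1825
  min_interval_days: 0
- vaccine: Rota
  dose_number: 1
  visit_number: 2
  scheduled_age_days: 42
  min_age_days: 42
  max_age_days: 364
  min_interval_days: 0
- vaccine: OPV
  dose_number: 2
  visit_number: 3
  scheduled_age_days: 70
  min_age_days: 70
  max_age_days: 1825
  min_interval_days: 28
- vaccine: Penta
  dose_number: 2
  visit_number: 3
  scheduled_age_days: 70
  min_age_days: 70
  max_age_days: 1825
  min_interval_days: 28
- vaccine: PCV
  dose_number: 2
  visit_number: 3
  scheduled_age_days: 70
  min_age_days: 70
  max_age_days: 1825
  min_interval_days: 28
- vaccine: Rota
  dose_number: 2
  visit_number: 3
  scheduled_age_days: 70
  min_age_days: 70
  max_age_days: 364
  min_interval_days: 28
- vaccine: OPV
  dose_number: 3
  visit_number: 4
  scheduled_age_days: 98
  min_age_days: 98
  max_age_days: 1825
  min_interval_days: 28
- vaccine: Penta
  dose_number: 3
  visit_number: 4
  scheduled_age_days: 98
  min_age_days: 98
  max_age_days: 1825
  min_interval_days: 28
- vaccine: PCV
  dose_number: 3
  visit_number: 4
  scheduled_age_days: 98
  min_age_days: 98
  max_age_days: 1825
  min_interval_days: 28
- vaccine: MCV
  dose_number: 1
  visit_number: 5
  scheduled_age_days: 274
  min_age_days: 274
  max_age_days: 1825
  min_interval_days: 0
- vaccine: MCV
  dose_number: 2
  visit_number: 6
  scheduled_age_days: 548
  min_age_days: 548
  max_age_days: 1825
  min_interval_days: 28
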