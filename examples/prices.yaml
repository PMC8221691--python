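# Two named price sets: "reference" is the default used in analyses,
# "alternate" supports the price-swap sensitivity analysis.  All values are
# illustrative/synthetic stand-ins on the scale of published standard-cost
# manuals; unit costs are money per unit (per night / visit / unit / hour),
# informal_care_wage is money per hour, facility per-diems money per day,
# hospital_los mean nights per admission.  The recorded-days country
# registers hospital admission days directly and needs no LOS entry.
price_tables:
  - name: reference
    currency: EUR
    year: 2014
    unit_costs:
      hospital_night: 480.0
      er_visit: 260.0
      physician_visit: 33.0
      supportive_unit: 25.0
      other_hc_unit: 40.0
      home_care_hour: 50.0
      therapist_hour: 38.0
    informal_care_wage: 14.0
    facility_per_diem:
      nursing_home: 170.0
      hospital: 480.0
      rehabilitation: 230.0
    hospital_los: {NL: 6.1, IT: 7.8, IS: 5.9, FI: 7.0, DE: 9.2}
    recorded_days_country: BE
  - name: alternate
    currency: EUR
    year: 2015
    unit_costs:
      hospital_night: 590.0
      er_visit: 240.0
      physician_visit: 21.0
      supportive_unit: 18.0
      other_hc_unit: 33.0
      home_care_hour: 22.0
      therapist_hour: 25.0
    informal_care_wage: 9.0
    facility_per_diem:
      nursing_home: 105.0
      hospital: 590.0
      rehabilitation: 160.0
    hospital_los: {NL: 6.1, IT: 7.8, IS: 5.9, FI: 7.0, DE: 9.2}
    recorded_days_country: BE
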