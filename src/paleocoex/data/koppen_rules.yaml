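# Köppen-Geiger rule thresholds (Peel-style variant) used by
# paleocoex.biogeography.koppen_classify.  Restricted to the extratropical
# C/D/E families with f/s/w precipitation and a/b/c temperature modifiers.
# Temperatures in deg C, precipitation in mm/month.
polar:
  hottest_month_max: 10.0        # E family when hottest month < 10
  tundra_hottest_min: 0.0        # ET when 0 < hottest <= 10, EF otherwise
continental:
  coldest_month_max: 0.0         # D family when coldest month <= 0
temperate:
  coldest_month_min: 0.0         # C family when 0 < coldest < 18
  coldest_month_max: 18.0
precipitation:
  dry_summer_mm: 40.0            # s: driest summer month < 40 mm and
  dry_summer_winter_ratio: 3.0   #    < wettest winter month / 3
  dry_winter_summer_ratio: 10.0  # w: driest winter month < wettest summer month / 10
temperature_modifier:
  hot_summer_min: 22.0           # a: hottest month >= 22
  warm_summer_months: 4          # b: >= 4 months with mean >= 10
  month_threshold: 10.0
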