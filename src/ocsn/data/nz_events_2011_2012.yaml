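# Default event calendar for week exclusion: New Zealand public holidays
# (national; Mondayised observances included) and World Smokefree Day
# (31 May) for 2011-2012.  Edit or replace via the holidays= argument.
events:
  # 2011
  - 2011-01-01  # New Year's Day (Sat)
  - 2011-01-02  # Day after New Year's Day (Sun)
  - 2011-01-03  # New Year's Day observed
  - 2011-01-04  # Day after New Year's Day observed
  - 2011-02-06  # Waitangi Day (Sun)
  - 2011-04-22  # Good Friday
  - 2011-04-25  # Easter Monday / Anzac Day
  - 2011-04-26  # Easter Tuesday observance gap (Anzac carried)
  - 2011-05-31  # World Smokefree Day
  - 2011-06-06  # Queen's Birthday
  - 2011-10-24  # Labour Day
  - 2011-12-25  # Christmas Day (Sun)
  - 2011-12-26  # Boxing Day
  - 2011-12-27  # Christmas Day observed
  # 2012
  - 2012-01-01  # New Year's Day (Sun)
  - 2012-01-02  # New Year's Day observed
  - 2012-01-03  # Day after New Year's Day observed
  - 2012-02-06  # Waitangi Day
  - 2012-04-06  # Good Friday
  - 2012-04-09  # Easter Monday
  - 2012-04-25  # Anzac Day
  - 2012-05-31  # World Smokefree Day
  - 2012-06-04  # Queen's Birthday
  - 2012-10-22  # Labour Day
  - 2012-12-25  # Christmas Day
  - 2012-12-26  # Boxing Day
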