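"""Seasonal arrivals and the day-of-week activity profile.

Monthly counts of first-time posts (with exact Poisson intervals) expose the
New-Year arrival peak and December trough; a weekly-cluster-adjusted GEE fit
of daily totals exposes the work-week high, Friday dip and weekend low.
"""

import ocsn

cfg = ocsn.SimConfig(n_users=2000, seed=0)
stream, _ = ocsn.simulate_network(cfg)

monthly = ocsn.first_time_post_series(stream)
by_month = monthly["count"].groupby(monthly.index.month).sum()
print("first-time posts by calendar month (2011+2012):")
print("  " + " ".join(f"{m}:{c}" for m, c in by_month.items()))

events = ocsn.load_event_calendar()  # bundled NZ holidays + World Smokefree Day
fit = ocsn.weekday_adjusted_means(ocsn.daily_series(stream), events)
print(f"\nweekday means over {fit.n_weeks} weeks "
      f"({len(fit.excluded_weeks)} holiday weeks excluded):")
for row in fit.table.itertuples():
    star = " ***" if row.p_vs_monday < 0.001 else ""
    print(f"  {row.weekday:9s} {row.mean:7.1f} "
          f"[{row.ci_low:6.1f}, {row.ci_high:6.1f}]{star}")

# January dominates arrivals and December is the trough; Saturday and Sunday
# run far below Monday (*** marks p<0.001 vs Monday, cluster-robust).
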