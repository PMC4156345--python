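"""Classify users into HEU / MEU / OTHER and estimate contribution shares.

A Highly Engaged User makes 180+ items in some 90-day window of the year;
a Minimally Engaged User never exceeds 2. Shares of all items come with
percentile-bootstrap 95% intervals from resampling users.
"""

import ocsn

cfg = ocsn.SimConfig(n_users=2000, seed=0)
stream, _ = ocsn.simulate_network(cfg)

timelines = ocsn.build_timelines(stream)
cls = ocsn.classify(timelines, year=2012)

print(f"users active in 2012: {len(cls.table)}")
for est in ocsn.contribution(cls, stream, n_boot=2000, seed=0):
    print(f"  {est.group:5s}: {est.n_users:5d} users "
          f"({100 * est.share_users:4.1f}%) contribute "
          f"{100 * est.share_items:4.1f}% of items "
          f"[±{100 * est.half_width:.1f}%]")

dyn = {d.group: d for d in ocsn.group_dynamics(
    ocsn.classify(timelines, 2011), cls)}
h = dyn["HEU"]
print(f"HEU growth 2011->2012: {h.n_a} -> {h.n_b} ({h.pct_growth:+.0f}%), "
      f"{h.overlap} in the group both years")

# A small highly engaged group contributes the majority of items while the
# large minimally engaged group contributes ~1%, the skew such networks show.
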