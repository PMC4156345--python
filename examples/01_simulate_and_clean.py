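"""Generate a synthetic support-network stream, corrupt it, and clean it.

The generator emits a realistic two-year interaction stream; artifact
injection then adds accidental verbatim re-submissions and staff replies.
The cleaning pipeline must recover exactly the original items.
"""

import ocsn

cfg = ocsn.SimConfig(n_users=500, seed=1)
stream, truth = ocsn.simulate_network(cfg)
raw, truth = ocsn.inject_artifacts(stream, cfg, truth)

cleaned, report = ocsn.clean_pipeline(raw, staff_ids=[ocsn.STAFF_USER_ID])

print(f"raw items:            {report.n_raw}")
print(f"duplicates removed:   {report.n_duplicates_removed}")
print(f"staff items removed:  {report.n_staff_removed}")
print(f"analysis set:         {report.n_final}")
print(f"recovered original:   {set(cleaned.df['item_id']) == truth.clean_item_ids}")

# Raw minus duplicates minus staff equals the analysis set; the final line
# confirms the survivors are exactly the items the generator marked clean.
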