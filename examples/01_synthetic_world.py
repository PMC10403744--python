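"""Generate a synthetic cohort, police register and event table.

The generator plants known error processes (nicknames, typos, stale
addresses, fake names, twins, identity fragmentation) and returns the
ground-truth pair table that the rest of the pipeline is judged against.
"""

from coplink import GenParams, generate_all

params = GenParams(n_cohort=1000, n_background=250, seed=42)
cohort, subjects, truth, events = generate_all(params)

print(f"cohort members:        {len(cohort)}")
print(f"register identities:   {len(subjects)}")
print(f"true (study, offender) pairs: {len(truth)}")
print(f"event rows after retention censoring: {len(events)}")

twins = sum(1 for r in cohort if r.twin_group)
print(f"twin individuals:      {twins}")

# show one deliberately corrupted identity next to its cohort record
by_id = {r.study_id: r for r in cohort}
for s in subjects:
    if s.truth_study_id and s.forename != by_id[s.truth_study_id].forename:
        person = by_id[s.truth_study_id]
        print("\nexample corrupted register identity:")
        print(f"  cohort:   {person.forename} {person.surname}  {person.dob}")
        print(f"  register: {s.forename} {s.surname}  {s.dob}")
        print("  (same person; the register holds a name variant or typo)")
        break
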