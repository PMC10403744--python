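"""Per-birthday residence flags: who was actually at risk of a local record.

A regional force only records local crime, so analyses need to know who
lived in the policing area at each age.  Flags mark each birthday from 10
(age of criminal responsibility) to 28 as in-area, out-of-area, or
address-unknown.
"""

from coplink import GenParams, generate_cohort
from coplink.denominator import cohort_residence_flags, denominator_summary
from coplink.pipeline import in_area_predicate

cohort = generate_cohort(GenParams(n_cohort=2000, seed=7))
flags = cohort_residence_flags(cohort, in_area_predicate)
summary = denominator_summary(flags)

print("share of the cohort resident in the policing area, by birthday:")
for age in (10, 14, 18, 22, 26, 28):
    print(f"  age {age}: {summary['per_age'][f'age{age}']:.1%}")
print(f"resident on every birthday 10..28: {summary['every_birthday']:.1%}")
print("(analyses of offending rates should restrict to these person-years)")
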