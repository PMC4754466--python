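"""Plateau ages and sex comparisons from published tract-level fits.

The exponential maturation model FA (or MD) = C + A exp(-age/t) levels off
at the age T = 6 + t ln 10, where 90% of the remaining change from age 6
toward the asymptote is complete.  This script recomputes T, its standard
error (ln 10 * se_t), and the annual change rate for every tract in the
bundled reference table, then applies the interval-overlap rule to find
tracts where females plateau significantly earlier than males.
"""

import tractmat as tm
from tractmat.reporting import round_half_away

ref = tm.load_reference_fits()

print(f"{'measure':8}{'tract':6}{'sex':4}{'t (y)':>7}{'T (y)':>8}{'se_T':>6}")
for _, row in ref.iterrows():
    T, se_T, in_window = tm.plateau_age(row["t"], row["se_t"])
    flag = "" if in_window else "  (beyond age 30)"
    print(f"{row['measure']:8}{row['tract']:6}{row['sex']:4}{row['t']:7.1f}"
          f"{round_half_away(T, 1):8.1f}{round_half_away(se_T, 1):6.1f}{flag}")

for measure in ("fa", "md"):
    sig = tm.sex_significant_tracts(ref, measure)
    print(f"\n{measure.upper()}: females plateau significantly earlier in "
          f"{sorted(sig)} (T ± SE intervals disjoint)")
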