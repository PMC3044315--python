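"""Choose the suppression depth tau by the condition number of Z.

Each candidate tau yields an independent-component matrix Z whose condition
number delta = S_max/S_min measures how evenly energy is spread over the
components; the smallest delta marks the most stable basis.  Numerical ties
resolve to the lowest tied threshold greater than 1.
"""

import micasel as mcs

profile = mcs.generate_two_class_profile(
    mcs.SyntheticSpec(p_per_class=20, n=512, effect_size=3.0, seed=9))

tau_star, deltas = mcs.select_level_threshold(
    profile, candidate_taus=[1, 2, 3, 4, 5], wavelet_name="db8", level=5,
    seed=9)

for tau in sorted(deltas):
    marker = "  <- selected" if tau == tau_star else ""
    print(f"tau={tau}: delta = {deltas[tau]:8.4f}{marker}")
print(f"\noptimal level threshold: tau* = {tau_star}")
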