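"""Load the bundled patient roster and randomize a presentation.

Shows the virtual-patient pool: ten authored base cases, a 100-name pool,
and the demographic randomization that multiplies them into >=1000 distinct
trainee-facing identities while leaving clinical ground truth untouched.
"""

from hearsim import count_profile_space, default_name_pool, default_roster, randomize_presentation

roster = default_roster()
pool = default_name_pool()

print(f"Base cases: {len(roster)}, name pool: {len(pool)}, "
      f"distinct identities: {count_profile_space(roster, pool)}")

base = roster[0]
for seed in (1, 2):
    pres = randomize_presentation(base, pool, seed)
    print(f"\nseed {seed}: {pres.display_name} ({pres.sex.value}, {pres.age_years})")
    print(f"  {pres.backstory}")
    assert pres.base.left == base.left and pres.base.right == base.right

print("\nBoth presentations carry the same clinical ground truth as the base case;")
print("only the name, sex, age and backstory differ.")
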