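"""Physiology generation: demographic conditioning, jitter, and hard caps.

Generates a mixed-age cohort and prints group means, demonstrating that
individuals who share (age, gender, ethnicity) share pre-jitter values,
that jitter differentiates them, and that height/weight never exceed the
225 cm / 160 kg caps.
"""

import numpy as np

from rpgen import generate_physiology, generate_population_physiology, jitter_physiology

# One adult male: all derived quantities are closed forms of height/weight.
p = generate_physiology(30, "M", "N", np.random.default_rng(42))
print(f"adult male example: height {p.height:.1f} cm, weight {p.body_weight:.1f} kg")
print(f"  BSA {p.body_surface_area:.2f} m2, cardiac output {p.cardiac_output:.0f} L/h,"
      f" breathing {p.breathing_rate:.1f} m3/day, blood {p.blood_volume:.1f} L")
j = jitter_physiology(p, np.random.default_rng(7))
print(f"  after jitter: height {j.height:.1f} cm, weight {j.body_weight:.1f} kg"
      " (derived quantities recomputed)")

# A 10,000-person cohort across ages 0-99.
rng = np.random.default_rng(1)
n = 10_000
ages = rng.integers(0, 100, size=n)
genders = np.where(rng.random(n) < 0.5, "M", "F")
eth = np.full(n, "N", dtype=object)
df = generate_population_physiology(ages, genders, eth, seed=77)
adults = df[ages >= 18]
children = df[ages < 18]
print(f"mean adult weight:  {adults['body_weight_kg'].mean():.1f} kg")
print(f"mean child weight:  {children['body_weight_kg'].mean():.1f} kg")
print(f"max height:         {df['height_cm'].max():.1f} cm  (cap 225)")
print(f"max weight:         {df['body_weight_kg'].max():.1f} kg  (cap 160)")
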