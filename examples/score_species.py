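"""Score the bundled 54-species table for collision and displacement risk.

The collision index weights blade-height exposure by the mean of the three
flight-behaviour factors and the conservation-importance total; the
displacement index multiplies disturbance susceptibility, habitat
specialisation and conservation importance (scaled by 10).  Both round
half-to-even.  Higher means more sensitive; the two scales are only
comparable as rankings, not values.
"""

from seasens import ssi

rows = ssi.load_species_scores()
table = ssi.score_table(rows)

print("Top 5 collision-sensitive species:")
print(table[["species", "collision_score", "collision_class"]]
      .head(5).to_string(index=False))

disp = table.sort_values("displacement_score", ascending=False, kind="stable")
print("\nTop 5 displacement-sensitive species:")
print(disp[["species", "displacement_score", "displacement_class"]]
      .head(5).to_string(index=False))

hg = table.set_index("species").loc["Herring gull"]
print(f"\nHerring gull: collision {hg.collision_score} ({hg.collision_class}),"
      f" displacement {hg.displacement_score} ({hg.displacement_class}),"
      f" overall category {hg.overall_cat}")
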