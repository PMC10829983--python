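"""Find joint entities — entities recurring across many distinct triplets.

Plants three hub entities at an exact (subject, object) degree of (4, 3)
and recovers them with the key(4,3) constraint.  The enumeration shows
that a constraint level n admits 2n+1 key combinations.
"""
from mlrkg import (
    JointConstraint,
    deduplicate,
    entity_degrees,
    enumerate_constraints,
    find_joints,
    overlap_classes,
)
from mlrkg.synthetic_fixtures import FixtureConfig, generate

hubs = tuple((name, 4, 3) for name in ("tiotropium", "budesonide", "reslizumab"))
_, table, _ = generate(
    FixtureConfig(n_sentences=3 * 7 + 30, planted_joints=hubs,
                  p_incomplete=0, p_duplicate=0, keyword_fraction=0, seed=2)
)

degrees = entity_degrees(deduplicate(table))
classes = overlap_classes(degrees)

print("key(a,b) combinations at level 3:",
      [(c.subj_required, c.obj_required) for c in enumerate_constraints(3)])
joints = find_joints(degrees, JointConstraint(4, 3))
print(f"entities at exactly (4 subject, 3 object) occurrences: {joints}")
for name in joints:
    print(f"  {name}: colour class {classes[name]}")
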