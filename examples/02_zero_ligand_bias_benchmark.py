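"""Build a zero-ligand-bias benchmark and show that it defeats ligand bias.

Identical ligands (matched by InChI-Key) bound to different pockets are
clustered; clusters with mean pK in [6, 7] and sample variance > 1 form
the test set, so per-ligand memorization cannot score well.  A ligand-view
baseline trained on separate pocket-signal data collapses to R near 0 on
this benchmark while the pocket view stays predictive.
"""

import numpy as np

import sfprobe as sp

cfg = sp.GeneratorConfig(alpha_ligand=0.0, beta_pocket=1.0, seed=11)
testbed, truth = sp.generate_zero_bias_testbed(cfg)
split = sp.zero_ligand_bias_filter(testbed)
sp.validate_split(split, testbed)
planted = set(sum(truth.plan["planted"].values(), []))
print(f"filter kept {len(split.test_ids)} complexes; "
      f"planted clusters recovered exactly: {split.test_ids == planted}")

train_cfg = sp.GeneratorConfig(n_complexes=300, alpha_ligand=0.0, beta_pocket=1.0, seed=99)
train, _ = sp.generate_records(train_cfg)
test = [r for r in testbed if r.complex_id in split.test_ids]
y = np.array([r.label.pk for r in test])
config = sp.TrainConfig(seed=0, search_budget=1)
for view in ("pocket", "ligand"):
    model = sp.train_bias_model(train, view, config)
    pred = np.array([p for _, p in sp.predict(model, test)])
    print(f"{view:>6}-view baseline on the zero-ligand-bias set: "
          f"R = {sp.pearson_r(y, pred):+.3f}")

print("\nOnly pocket information scores on this benchmark: a model beating")
print("the pocket-view baseline here has learned more than dataset bias.")
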