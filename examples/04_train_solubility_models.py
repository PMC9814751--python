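"""Fit and evaluate the good-solvent classifier on a planted-rule dataset.

A synthetic evaluation table whose labels follow a known structure-
solubility rule is run through the repeated-split random-forest protocol
(random 80/20 splits, cross-validated grid search per split), and the
Boruta-style shadow-feature procedure recovers the planted feature.
"""

import numpy as np

from solucover import (MLProtocol, SpaceSpec, important_features,
                       run_protocol, synth_solubility_table, synth_space)

space = synth_space(SpaceSpec(n_molecules=20, n_clusters=2, nbits=32, n_on=8,
                              intra_cluster_flip=0.0, seed=0))[0]
rule = np.zeros(48)
planted_bit = next(iter(space.fingerprints[0].bits))
rule[planted_bit] = 5.0
X, table, truth = synth_solubility_table(space, 12, rule, noise=0.0, seed=0,
                                         threshold=2.5)

protocol = MLProtocol(n_iterations=10, n_estimators_grid=(100,),
                      max_depth_grid=(4, 8), seed=0)
report = run_protocol(X, table, "classify_good", protocol)
print(f"{len(table)} molecule-solvent pairs, "
      f"{int(table['label_good'].sum())} good-solvent labels")
print("\nclassification summary (mean over iterations):")
print(report.summary.round(3).to_string())

decisions = important_features(X, table, "classify_good", n_trials=15, seed=0)
confirmed = [d for d in decisions if d.status == "confirmed"]
print(f"\nBoruta: {len(confirmed)} confirmed feature(s); "
      f"planted bit {planted_bit} confirmed: "
      f"{any(d.index == planted_bit for d in confirmed)}")
# Test accuracy near 1.0 and a single confirmed feature show the protocol
# recovers the planted rule rather than memorizing the split.
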