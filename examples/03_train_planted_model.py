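"""Train the region model on a planted-signal corpus and compare baselines.

Generates a synthetic corpus in which a single feature token marks the
functional region of every positive protein (only protein-level labels
are seen in training, with 5% noise), trains the four-term group-instance
cost function starting from the whole-protein logistic seed, and measures
how well each model localizes the function to the correct regions.
"""

from regionfp.pipeline import run_planted_experiment
from regionfp.synthetic_fixtures import SyntheticSpec

spec = SyntheticSpec(n_proteins=200, label_noise=0.05, seed=1)
run = run_planted_experiment(seed=1, spec=spec)

n_pos = sum(run.corpus.protein_labels.values())
print(f"corpus: {len(run.corpus.proteins)} proteins "
      f"({n_pos} positive), {len(run.corpus.region_ids)} regions")
print(f"feature space: {run.model.space.value}, vocabulary "
      f"{len(run.encoded.region_matrix.vocabulary)} tokens")
print(f"kernel threshold: {run.encoded.kernel.threshold:.3f}")
print(f"baseline ridge weight chosen on validation: {run.baseline_lam}")
print(f"training stopped at epoch {run.fit_result.best_epoch} "
      f"(final cost {run.fit_result.loss_trace[-1]:.4f})")

print("\nregion-level AUPR against structure-derived binding labels:")
print(f"  region-specific model : {run.region_aupr_gicf:.4f}")
print(f"  whole-protein baseline: {run.region_aupr_baseline:.4f}")
print("the gap is the value of training with region-level constraints: "
      "the baseline spreads label-correlated family features over every "
      "region, the region model localizes them")
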