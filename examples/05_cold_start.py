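"""Cold-start evaluation: leave-one-drug-out.

The held-out drug never appears in training; the model must infer its
behaviour from its fingerprint similarity to the reference drugs and its
target/pathway annotations.  Cold-start metrics are expected to be worse
than combination-disjoint metrics — the drug itself, not just the pair,
is unseen.
"""

from synfuse.experiments import autoencoder_spec, fixture_spec, model_config
from synfuse.pipeline import run_experiment
from synfuse.simulate import generate_fixture

fixture = generate_fixture(fixture_spec(seed=4))
result = run_experiment(
    fixture, model_config(seed=4), autoencoder_spec(seed=4),
    split_strategy="leave_one_drug_out",
    folds_to_run=[0, 1, 2],  # three held-out drugs, for speed
)
for fold in result["per_fold"]:
    print(f"held-out drug #{fold['fold']}: "
          f"n={fold['n']}  mse={fold['mse']:.3f}  pcc={fold['pcc']:.3f}")
pooled = result["pooled"]
print(f"pooled over held-out drugs: mse={pooled['mse']:.3f} "
      f"pcc={pooled['pcc']:.3f}")
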