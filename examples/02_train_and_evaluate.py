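"""Train the masked GNN on a multimodal cohort and evaluate it.

Simulates 200 subjects whose cognition-like score depends on two
functional edges, then splits 70/10/20, trains with the default
hyperparameters (Adam, lr 0.005, batch 32, 50 epochs, plateau LR
decay) and reports test RMSE/MAE.
"""

import numpy as np

from maskgnn.objective import LossConfig
from maskgnn.synthetic import SyntheticCohortSpec, generate_cohort
from maskgnn.training import TrainConfig, prepare_samples, run_experiment

spec = SyntheticCohortSpec(
    n_subjects=200, n_rois=20, planted_edges=((0, 5), (1, 7)), noise_sd=0.1, seed=42
)
subjects = generate_cohort(spec)
labels = np.array([s.score for s in subjects])
print(f"cohort: {len(subjects)} subjects, label sd {labels.std():.3f}")

samples = prepare_samples(subjects, mode="fc_sc", use_as=True)
params, history, report = run_experiment(
    samples, LossConfig(task="regression"), TrainConfig(seed=1)
)
print(f"training loss: {history[0]['train_prediction']:.3f} (epoch 0) -> "
      f"{history[-1]['train_prediction']:.3f} (epoch {history[-1]['epoch']})")
print(f"test RMSE {report.metrics['rmse']:.3f}, MAE {report.metrics['mae']:.3f} "
      f"on {report.n_samples} held-out subjects")
# RMSE well below the label sd means the model recovered a large part
# of the planted functional-edge signal from the connectivity features.
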