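"""Two agents in a shared world drift into generalized synchrony.

Both agents track the same ring-world token through noisy private
observations, model each other's actions (depth-1 theory of mind), and
start from sharply divergent priors.  Mutual tracking of the shared
state pulls their beliefs together.
"""

import numpy as np

from protentia.fixtures import make_shared_world
from protentia.multiagent import simulate_ensemble, synchrony_trace

bundle = make_shared_world(n_agents=2, n_sites=5, overlap=1, seed=3)
traj = simulate_ensemble(bundle.env, list(bundle.agents), T=80,
                         rng=np.random.default_rng(7))
trace = synchrony_trace(traj)

print("step  pairwise-KL  prediction-logscore  total-F")
for row in trace[::10] + [trace[-1]]:
    print(f"{int(row['step']):4d}  {row['mean_pairwise_kl']:11.4f}  "
          f"{row['mean_prediction_logscore']:19.4f}  {row['total_free_energy']:7.3f}")

first = float(np.mean([r["mean_pairwise_kl"] for r in trace[:10]]))
last = float(np.mean([r["mean_pairwise_kl"] for r in trace[-10:]]))
print(f"\nMean pairwise belief KL (averaged over 10 steps) fell from "
      f"{first:.3f} to {last:.3f}.")
print("The instantaneous trace is noisy — a wrong observation briefly splits the")
print("beliefs — but shared observations of a shared world keep pulling the")
print("posteriors together: the operational signature of generalized synchrony.")
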