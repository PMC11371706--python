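"""Fit the multiblock OPLS, test effect significance, and select markers.

Runs the full per-dataset chain on a synthetic two-dataset study with 30
planted attractive-cultivar and 30 unattractive-cultivar marker features per
dataset, then scores how many planted markers the extreme-loading selection
recovered with the right direction.
"""

from amoplsnet import PipelineConfig, run_metabolomics
from amoplsnet.synthetic import generate_study

study = generate_study(seed=1, n_features=300, n_markers_per_side=30)
datasets = {name: ds["table"] for name, ds in study["datasets"].items()}

config = PipelineConfig(n_permutations=199, marker_k=30, seed=1)
bundle = run_metabolomics(datasets, study["attractiveness"], config=config)

for name, res in bundle.datasets.items():
    print(f"[{name}] cultivar-dominated component: {res.cultivar_component}")
    print(res.summary[["rss_pct", "p_value", "top_component"]].round(3))

m = bundle.markers
print(f"marker records: {m.n_records}, unique: {m.n_unique}, shared across datasets: {m.n_shared}")

correct = total = 0
for name, ds in study["datasets"].items():
    truth = ds["truth"].marker_direction
    found = {r.feature_id: r.direction for r in m.records if r.dataset == name}
    total += len(truth)
    correct += sum(1 for fid, d in truth.items() if found.get(fid) == d)
print(f"planted markers recovered with correct direction: {correct}/{total}")
# p-values ~0.005 for cultivar and date say the permutation test flags the
# planted effects at its resolution floor (1/(199+1)); the interaction,
# which was not planted, stays non-significant.
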