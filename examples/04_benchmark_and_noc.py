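"""Interaction-aware benchmarking: per-click tables and clicks-to-threshold.

Uses untrained (random-weight) networks so it runs in seconds - the point
here is the protocol, not the scores: per-sample outcomes are averaged over
three simulator repeats before dataset aggregation, DSC is reported as
mean +- SD and HD95 as median/IQR at 0/1/5/10 clicks, and NoC/PoF count the
clicks needed to reach DSC 0.75/0.85 or HD95 5.0/2.5 mm within a 20-click
budget.  Swap in trained checkpoints for meaningful numbers.
"""

from clickseg import NetworkConfig, PhantomSpec, build_network, generate_dataset
from clickseg.evaluation import run_benchmark
from clickseg.session import TwoStageSegmenter

spec = PhantomSpec(shape=(32, 32, 32), tumor_radius_range=(4.0, 7.0),
                   distractor_count=2, distractor_radius_range=(1.5, 2.5))
test = generate_dataset(4, spec, seed=99)

segmenter = TwoStageSegmenter(
    build_network(NetworkConfig.desk_scale(2), seed=1),
    build_network(NetworkConfig.desk_scale(5), seed=2),
)
tables = run_benchmark({"two-stage (untrained)": segmenter}, test,
                       T=10, repeats=3, seeds=[0, 1, 2],
                       avg_range=(0, 10))
print(tables["per_click"].round(3).to_string(index=False))
print()
print(tables["noc"].round(2).to_string(index=False))
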