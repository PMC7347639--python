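"""How search-market size degrades the proxy: the censoring ladder.

Smaller markets sit closer to the feed's display threshold (more days
reported as 0) and their sampled series are noisier; both scale with
market volume. Each rung of the ladder is a calibrated volume level.
(Reduced panel size here to keep the example quick; the reproduction
script runs 100 site-years per level.)
"""

from pollenproxy.experiments import censoring_experiment

levels = censoring_experiment(seed=1, n_per_level=30)

print(f"{'zero days target':>16} {'achieved':>9} {'noise cv':>9} {'median rho':>11}")
for level in levels:
    print(
        f"{level.target_zero_pct:15.0f}% {level.median_zero_pct:8.1f}% "
        f"{level.noise_cv:9.3f} {level.median_rho:11.3f}"
    )
print("\nMedian rho declines as censoring (and the sampling noise that")
print("accompanies a small market) increases - the data-volume effect.")
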