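"""Run the default 100-scenario sweep and print the headline statistics.

The sweep cross-combines five consumer radii, four producer radii and five
surface-to-surface gaps (20 size combinations per gap).  Every scenario is
solved with the analytic image-charge engine; the summary reports how much
uptake a consumer loses by detaching from its producer, and how strongly
small consumers benefit from attachment once uptake is normalized to cell
volume.
"""

from n2oflux import build_default_sweep, run_sweep, summarize

grid = build_default_sweep()
table = run_sweep(grid, engine="analytic")
report = summarize(table)

print(f"scenarios solved:              {len(table)}")
print(f"size combinations:             {report.n_combinations}")
print(f"mean reduction, gap 0->0.1 um: {100 * report.mean_reduction_0_to_0p1:.1f}%")
print(f"mean reduction, gap 0->2 um:   {100 * report.mean_reduction_0_to_2:.1f}%")
print(f"max  reduction, gap 0->2 um:   {100 * report.max_reduction_0_to_2:.1f}%")
print(f"volnorm fold, ratio 0.1 -> 1:  {report.attached_fold_ratio_0p1_to_1:.0f}x")
print()
print("Moving a consumer just 0.1 um off its producer already costs it most")
print("of the locally elevated N2O; at 2 um it is effectively in bulk water.")
print("The fold change shows why only much-smaller-than-host cells profit")
print("from attachment once resource needs are scaled to cell volume.")
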