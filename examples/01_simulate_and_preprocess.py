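"""Generate a synthetic visual-search dataset and run the exclusion
cascade.

The generator reproduces the block design of a pop-out search study
(10 experimental blocks x 122 trials, 22 practice trials, 2 warm-ups per
block) and draws each trial from a seven-parameter diffusion process with
a repetition advantage in drift rate and non-decision time, plus fast
guesses and slow lapses to give the filters something to do.
"""

from rtseq import (
    DesignSpec,
    FilterConfig,
    code_sequence,
    default_ground_truth,
    determine_lower_bound,
    filter_trials,
    simulate_dataset,
)

spec = DesignSpec("visual_search")
truth = default_ground_truth("visual_search", seed=1)
table, truth = simulate_dataset(spec, truth, n_participants=4, seed=1)
print(f"simulated {len(table)} trials from {table.df['participant'].nunique()} participants")

coded = code_sequence(table)  # label repetition / alternation before filtering
lower = determine_lower_bound(coded)
print(f"adaptive lower RT cutoff: {lower:.0f} ms "
      "(first of two successive 50 ms bins above chance accuracy)")

filt, report = filter_trials(coded, FilterConfig(lower_rt_ms=lower))
print(f"excluded {report.fraction_excluded:.1%} of trials:")
for rule, n in report.n_excluded_by_rule.items():
    print(f"  {rule:>10}: {n}")
print(f"{report.n_survivors} trials survive; these feed every later analysis")
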