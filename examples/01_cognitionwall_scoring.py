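"""Score one simulated subject's discrimination/reversal learning.

A softmax Rescorla-Wagner agent with a left bias works the FR5 task for
four days; the reversal to the right entrance happens 50.5 h in.  We score
entrance bias, entries-to-criterion in both phases, and reversal errors.
"""

from phenocage.cognitionwall import (
    classify_rl_errors,
    entrance_bias,
    entries_to_criterion,
    fr5_reward_ledger,
    split_phases,
    split_rl_days,
)
from phenocage.core import TaskSchedule
from phenocage.simulate import AgentParams, simulate_cognitionwall

schedule = TaskSchedule()
stream = simulate_cognitionwall(AgentParams(), schedule, seed=7)
print(f"{len(stream)} entries over {stream.t[-1] / 3600:.1f} h")

bias = entrance_bias(stream)
print("entrance bias (first 30, unrewarded):",
      {k: round(v, 2) for k, v in bias.items()})
# >1/3 on the left reflects the built-in side preference the task exploits

dl, rl = split_phases(stream)
dl_result = entries_to_criterion(dl, schedule.target_dl)
rl_result = entries_to_criterion(rl, schedule.target_rl)
print(f"DL criterion (80% of last 30) reached at entry {dl_result.entries_to_criterion}")
print(f"RL criterion reached at entry {rl_result.entries_to_criterion} "
      f"(censored: {rl_result.censored})")

rewards = fr5_reward_ledger(dl, schedule.target_dl)["rewarded"].sum()
print(f"pellets earned during DL: {rewards} (one per {schedule.fr} correct entries)")

rl1, rl2 = split_rl_days(rl)
for day, sub in (("RL1", rl1), ("RL2", rl2)):
    err = classify_rl_errors(sub, schedule.target_dl, schedule.target_rl, day)
    print(f"{day}: {err.perseverative} perseverative (old entrance), "
          f"{err.neutral} neutral (middle), {err.correct} correct")
# perseverative errors should drop from RL1 to RL2 as the agent re-learns
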