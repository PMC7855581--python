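"""Dark-light box metrics from a simulated session.

The mouse starts in the dark; the door opens after one minute and the
10-minute scoring window begins.  Latency to the light, total time in the
light and the number of light visits are the anxiety readouts — a more
anxious animal enters later, stays less, visits less.
"""

from phenocage.dlb import dlb_metrics
from phenocage.simulate import simulate_dlb

track, truth = simulate_dlb(latency_rate=1 / 20.0, bout_means=(45.0, 90.0),
                            seed=5)
metrics = dlb_metrics(track)

print(f"latency to light: {metrics.latency_to_light_s:.1f} s "
      f"(generator truth {truth['latency_s']:.1f} s)")
print(f"time in light:    {metrics.time_in_light_s:.1f} s of 600 "
      f"(truth {truth['time_in_light_s']:.1f})")
print(f"visits to light:  {metrics.visits_to_light} (truth {truth['visits']})")
# the scorer sees the 12.5 Hz sampled track, so times can differ from the
# continuous truth by up to one sample interval per bout boundary
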