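"""From one breast's runs to a 4x4 segment table and a diagnosis.

Averages the frequency of interest over the 16 surface segments (4 clock
quadrants x 4 height bands, boundary 5% trimmed, runs screened and averaged)
and applies the control-segment tolerance criterion: any segment deviating
from its band's control by more than 34% flags the breast as cancerous.
"""

import numpy as np

from dietfreq import phantom, pipeline
from dietfreq.diagnosis import diagnose, preset_configurations

material = phantom.MaterialSpec(stiffness_ratio=8.0)
tumor = phantom.TumorSpec(clock_position=6.0, depth=30.0, diameter=40.0)
breast = phantom.BreastSpec("demo", "left", volume=500.0, n_points=600, label="cancerous")

recordings = [
    phantom.synth_recording(
        breast,
        phantom.RecordingParams(input_frequency=f, seed=50 + i),
        material,
        tumor,
        cloud_seed=99,
    )
    for i, f in enumerate([20.0, 21.0, 22.0, 23.0])
]

analysis = pipeline.analyze_breast(recordings)
print("runs used:", analysis.runs_used)
print("segment mean frequencies of interest (rows = radial, cols = z-band):")
print(np.round(analysis.table.mean_foi, 1))

config6 = preset_configurations()[5]
outcome = diagnose(analysis.table, config6, tolerance=0.34)
worst = max(outcome.comparisons, key=lambda c: c.deviation)
print(f"\nconfiguration {config6.id}, tolerance 34%: "
      f"{'POSITIVE' if outcome.is_positive else 'negative'} "
      f"({len(outcome.flagged)} of {outcome.n_comparisons} comparisons flagged; "
      f"worst deviation {worst.deviation:.0%} at radial {worst.radial}, "
      f"z-band {worst.zband})")
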