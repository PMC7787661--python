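"""Fitts' law from stochastic planning alone (no motor noise anywhere).

Sweeps five target widths at fixed amplitude A = 0.15 m, runs a small
ensemble of independent trajectory optimizations per width, and fits
MD = a + b * log2(2A/W).  Movement durations lengthen and become more
variable as the index of difficulty rises, because fewer good control
solutions survive the tighter accuracy constraint — the slope b lands in
the range measured in human pointing experiments (0.039-0.199 s/bit).

(The full 10-width x 10-run protocol is run by scripts/acceptance.py;
this example is a 2-minute appetizer.)
"""

import numpy as np

from reachopt.experiments import FittsConfig, run_fitts
from reachopt.optimizer import OptimizerConfig

cfg = FittsConfig(widths=tuple(np.geomspace(0.16, 0.0141, 5)),
                  runs_per_width=5)
res = run_fitts(cfg, OptimizerConfig.reduced(), base_seed=0)

print(res.to_frame().to_string(index=False,
                               float_format=lambda x: f"{x:.3f}"))
print(f"\nFitts fit: MD = {res.a:.3f} + {res.b:.3f} * ID   "
      f"(R^2 = {res.r_squared:.3f})")
print("slope b is s/bit; mean MD rises and its SD grows as widths shrink")
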