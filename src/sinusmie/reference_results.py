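"""Published reference AUPRC values for maxillary-sinus anomaly
classification on the HCHS cohort.

These are the reported mean AUPRC values per 3D architecture under three
regimes — single-sample baseline (N=1), centroid sampling (N=15), and
sampling with multiple-instance ensembling (N=15 + MIE), all at patch size
P=35 — together with the sampling-type ablation values.  They serve as
inputs to the report arithmetic (percentage-increase and relative-decrease
summaries); this package does not claim to reproduce them from raw data,
which is not public.
"""

from __future__ import annotations

import pandas as pd

#: rows: architecture; columns: family, baseline (N=1), sampled (N=15),
#: sampled_mie (N=15 + MIE); values are mean AUPRC.
ARCHITECTURE_AUPRC = pd.DataFrame(
    [
        ("resnet3d", "ResNet18", 0.80, 0.88, 0.92),
        ("resnet3d", "ResNet50", 0.72, 0.82, 0.85),
        ("resnet3d", "ResNet101", 0.73, 0.85, 0.90),
        ("resnet3d", "ResNet152", 0.66, 0.83, 0.89),
        ("resnet3d", "ResNet200", 0.60, 0.86, 0.90),
        ("densenet3d", "DenseNet121", 0.86, 0.86, 0.92),
        ("densenet3d", "DenseNet169", 0.81, 0.91, 0.94),
        ("densenet3d", "DenseNet201", 0.88, 0.88, 0.93),
        ("densenet3d", "DenseNet264", 0.84, 0.88, 0.93),
    ],
    columns=["family", "architecture", "baseline", "sampled", "sampled_mie"],
)

#: Sampling-type ablation (equidistant variants at N=15): mean AUPRC when
#: all three axes vary versus when one axis is pinned at its mean.
SAMPLING_TYPE_AUPRC = {
    "equidistant_all_axes": 0.89,
    "equidistant_y_fixed": 0.88,
    "equidistant_z_fixed": 0.89,
    "gaussian": 0.92,
}
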