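#!/usr/bin/env python
"""Criterion instability: attenuation of one-interval but not 2afc d'.

Between-subject criterion jitter (tau) violates the stable-criterion
assumption behind the pooled one-interval analysis: the group hit and
false-alarm rates flatten, and the estimated detection d' shrinks by
1/sqrt(1 + tau^2).  The 2afc location estimate involves no detection
criterion and is untouched — which is why pooled one-interval estimates
are conservative.  Writes results/criterion_jitter.csv.
"""

import math
from pathlib import Path

from ibsdt import ObserverModelParams, SimulationConfig, criterion_jitter_study

OUT = Path(__file__).resolve().parents[1] / "results" / "criterion_jitter.csv"


def main() -> None:
    params = ObserverModelParams(
        detection_dprime=2.0, mean_criterion=0.45, location_dprime=0.5
    )
    table = criterion_jitter_study(
        params, [0.0, 0.25, 0.5, 1.0, 2.0], SimulationConfig("exp5", 50_000, seed=2026)
    )
    table["predicted_detection_dprime"] = [
        2.0 / math.sqrt(1 + t * t) for t in table.tau
    ]
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(
        "\ndetection d' follows the 1/sqrt(1+tau^2) attenuation while the "
        "2afc location d' stays at its true value 0.5"
    )
    OUT.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT, index=False)
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
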