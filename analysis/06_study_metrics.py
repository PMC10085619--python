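"""Bench-side formulas on a small synthetic measurements table: caliper
tumor volumes (width^2 x length x 0.5) per animal and day, and a worked
co-culture proliferation-rate example.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from revscreen import (
    CocultureCounts,
    add_tumor_volumes,
    relative_proliferation_rate,
)

SEED = 1
RESULTS = Path("results/analysis")


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for group, growth in (("control", 1.35), ("treated", 1.15)):
        for animal in range(1, 5):
            width = rng.uniform(3.0, 4.0)
            for day in (7, 14, 21):
                width *= growth ** (7 / 7)
                length = width * rng.uniform(1.2, 1.6)
                rows.append({
                    "animal_id": f"{group[0]}{animal}", "day": day,
                    "width_mm": round(width, 2), "length_mm": round(length, 2),
                    "body_weight_g": round(rng.uniform(18, 22), 1),
                    "group": group,
                })
    table = add_tumor_volumes(pd.DataFrame(rows))
    table.to_csv(RESULTS / "06_tumor_volumes.tsv", sep="\t", index=False,
                 float_format="%.6g")

    day21 = table[table["day"] == 21].groupby("group")["volume_mm3"].mean()
    print("mean day-21 tumor volume (mm^3) by group:")
    for group, vol in day21.items():
        print(f"  {group}: {vol:.1f}")

    rate = relative_proliferation_rate(CocultureCounts(113, 50, 200))
    print(f"co-culture example: 113 total cells, 50 marker-positive, "
          f"200 in control -> proliferation rate {rate:.1f}% "
          f"({100 - rate:.0f}-point reduction)")


if __name__ == "__main__":
    main()
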